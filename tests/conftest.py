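import pytest

from invcoal.synthetic import generate_truth_scenario, generate_dataset

# scaled-down study-like scenario: five >0.5 Mb-equivalent inversions on a
# 6 Mb toy genome, 3 + 2 samples, so end-to-end runs stay fast
TINY_CONFIG = {
    "chromosomes": [("X", 2_000_000), ("4", 2_000_000), ("5", 2_000_000)],
    "inversions": [
        ("X", 200_000, 1_200_000, "B"),
        ("X", 500_000, 1_100_000, "A"),
        ("X", 1_100_000, 1_800_000, "B"),
        ("4", 300_000, 1_400_000, "B"),
        ("5", 400_000, 1_300_000, "B"),
    ],
    "n_a": 3,
    "n_b": 2,
}


@pytest.fixture(scope="session")
def tiny_scenario():
    return generate_truth_scenario(TINY_CONFIG, seed=5)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scenario):
    return generate_dataset(tiny_scenario, max_sim_length=50_000)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tiny_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    tiny_dataset.write(out)
    from invcoal.synthetic import generate_sv_calls

    t1, t2 = generate_sv_calls(tiny_dataset.scenario, seed=1)
    t1.to_csv(out / "caller1.tsv", sep="\t", index=False)
    t2.to_csv(out / "caller2.tsv", sep="\t", index=False)
    return out


def write_vcf(path, records, samples, fmt="GT:DP:RPL:RPR:SAF:SAR"):
    """Minimal VCF writer for test fixtures.

    ``records`` are (chrom, pos1, ref, alt, [per-sample format strings]).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1,length=1000000>\n")
        fh.write("##contig=<ID=chr2,length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for f in ("DP", "RPL", "RPR", "SAF", "SAR"):
            fh.write(f'##FORMAT=<ID={f},Number=1,Type=Integer,Description="count">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, cols in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t60\tPASS\t.\t{fmt}\t" + "\t".join(cols) + "\n"
            )
    return path
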