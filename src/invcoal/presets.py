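"""Published parameter estimates used as simulation presets.

Best-fit demographies for the two *Drosophila virilis*-group sister
species this pipeline was built around (64-bp blocks, colinear autosomal
intergenic background): the sympatric and allopatric interspecific
comparisons under the best IM model (migration from species A, *D.
montana*-like, into species B, *D. flavomontana*-like), and the
intraspecific comparison under strict divergence.  These serve as truth
values for parameter-recovery experiments and as defaults for the
synthetic generator.
"""

from .likelihood import DemographicParams

MU = 2.8e-9  # per site per generation
GENERATION_TIME = 1.0  # years

#: best-fit IM (A -> B), sympatric comparison
SYMPATRIC_IM = DemographicParams(735_000, 377_000, 1_388_000, 2_526_000, 1.29e-8, "IM_AB")
#: best-fit IM (A -> B), allopatric comparison
ALLOPATRIC_IM = DemographicParams(705_000, 382_000, 1_403_000, 2_539_000, 1.09e-8, "IM_AB")
#: strict divergence, intraspecific comparison (allopatric vs sympatric A)
INTRASPECIFIC_DIV = DemographicParams(1_087_000, 1_560_000, 858_000, 210_000, 0.0, "DIV")

#: scaled migration rates (M = 2 * Ne_recipient * m) as reported
SYMPATRIC_M_SCALED = 0.0097
ALLOPATRIC_M_SCALED = 0.0083

#: gene-conversion parameters of the inversion null
CONVERTED_SITES_RATE = 1.4e-5  # converted sites /bp/gen
GC_TRACT_MEAN = 390.0  # bp
GC_INITIATION_RATE = 3.59e-8  # /bp/gen
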