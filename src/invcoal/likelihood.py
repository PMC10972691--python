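"""Composite-likelihood machinery for DIV and IM models on the blockwise SFS.

The data unit is a 64/128-bp sequence block scored, for one diploid
individual per species, by four folded mutation-type counts:

* ``hetA``  -- heterozygous in species A only
* ``hetB``  -- heterozygous in species B only
* ``hetAB`` -- heterozygous in both (same two alleles)
* ``fixed`` -- homozygous for different alleles

Under the infinite-sites assumption within a block, each count is Poisson
with mean ``mu * L * ell`` where ``L`` is the total genealogical branch
length subtending leaf subsets of the corresponding class.  The probability
of a (truncated) count configuration is the expectation of the product of
the four Poisson terms over the genealogy distribution of the structured
coalescent: two extant populations that merge into an ancestral population
``t`` generations ago, optionally with constant unidirectional migration.

We compute these probabilities exactly by augmenting the 4-lineage
structured-coalescent Markov chain with the (capped) mutation counts and
taking matrix exponentials: mutations of type ``k`` are transitions that
increment count ``k`` at rate ``mu*ell`` per class-``k`` lineage, counts
above ``kmax`` pool into a residual category per type.  The chain runs in
two phases: a two-deme phase of length ``t`` (solved with a sparse
``expm``-times-vector product) and an ancestral single-deme phase run to
absorption at the MRCA (solved as a linear system).  A Monte-Carlo
genealogy sampler (``invcoal.mc``) provides an independent estimate of the
same table and serves as the test oracle.

All times are in generations and all rates per generation; effective sizes
are diploid numbers of individuals.  Migration direction bookkeeping:
``IM_AB`` means forwards-in-time migration of individuals from A into B
(probability ``m`` per B-individual per generation of being a new A
migrant), hence backwards in time lineages currently in B jump to A at
rate ``m``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import expm_multiply

__all__ = [
    "DemographicParams",
    "ConfigProbabilityTable",
    "FitResult",
    "bsfs_probabilities",
    "bsfs_probabilities_mc",
    "composite_loglik",
    "fit_model",
    "compare_models",
    "to_absolute",
    "to_scaled",
    "migrant_fraction",
    "gc_initiation_rate",
    "MU_DEFAULT",
    "GENERATION_TIME_DEFAULT",
]

MU_DEFAULT = 2.8e-9  # per site per generation (D. melanogaster spontaneous rate)
GENERATION_TIME_DEFAULT = 1.0  # years per generation

MODELS = ("DIV", "IM_AB", "IM_BA")

# mutation-type classes of an ancestral lineage subtending i A-leaves and
# j B-leaves (2 diploids = 2+2 leaves; folded, so (i,j) ~ (2-i,2-j))
HETA, HETB, HETAB, FIXED = 0, 1, 2, 3
_CLASS = {
    (1, 0): HETA, (1, 2): HETA,
    (0, 1): HETB, (2, 1): HETB,
    (1, 1): HETAB,
    (2, 0): FIXED, (0, 2): FIXED,
    (2, 2): -1,  # root lineage: mutations invisible
}


@dataclass(frozen=True)
class DemographicParams:
    """Demographic parameters in absolute units.

    ``ne_a``/``ne_b``/``ne_anc`` are diploid effective sizes, ``t`` the
    split time in generations, ``m`` the per-lineage per-generation
    migration probability (0 for DIV).  Scaled duals (``T`` in units of
    ``2*Ne_ref`` generations; ``M = 2*Ne_recipient*m``) are available via
    :func:`to_scaled`.
    """

    ne_a: float
    ne_b: float
    ne_anc: float
    t: float
    m: float = 0.0
    model: str = "DIV"

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not all(np.isfinite([self.ne_a, self.ne_b, self.ne_anc, self.t, self.m])):
            raise ValueError("non-finite demographic parameters")
        if min(self.ne_a, self.ne_b, self.ne_anc) <= 0:
            raise ValueError("effective sizes must be positive")
        if self.t < 0 or self.m < 0:
            raise ValueError("t and m must be non-negative")
        if self.model == "DIV" and self.m != 0:
            raise ValueError("DIV model requires m = 0")

    @property
    def ne_recipient(self) -> float:
        """Size of the forwards-in-time recipient population (B under IM_AB)."""
        return self.ne_b if self.model != "IM_BA" else self.ne_a


def to_scaled(params: DemographicParams, ne_ref: float | None = None) -> dict:
    """Return scaled duals {T, M, theta per site} for reporting.

    ``T`` is in coalescent units of ``2*ne_ref`` generations (default
    reference: the recipient population, the convention under which the
    migrant fraction ``1 - exp(-T*M)`` is evaluated); ``M = 2*Ne_recipient*m``.
    """
    ref = params.ne_recipient if ne_ref is None else ne_ref
    return {
        "ne_ref": ref,
        "T": params.t / (2.0 * ref),
        "M": 2.0 * params.ne_recipient * params.m,
    }


def to_absolute(T: float, ne_ref: float, g: float = GENERATION_TIME_DEFAULT) -> float:
    """Convert a scaled split time to absolute time: ``t = T * 2*Ne * g``."""
    return T * 2.0 * ne_ref * g


def ne_from_theta(theta: float, mu: float = MU_DEFAULT) -> float:
    """Diploid effective size from per-site theta: ``Ne = theta / (4 mu)``."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return theta / (4.0 * mu)


def migrant_fraction(T: float, M: float) -> float:
    """Total probability that a recipient lineage traces back to the donor
    via migration before the split: ``1 - exp(-T*M)`` with ``T`` in units of
    ``2*Ne_recipient`` generations and ``M = 2*Ne_recipient*m``."""
    if T < 0 or M < 0:
        raise ValueError("T and M must be non-negative")
    return 1.0 - np.exp(-T * M)


def gc_initiation_rate(converted_sites_rate: float, mean_tract: float) -> float:
    """Gene-conversion initiation rate per base per generation from the rate
    of converted sites per base per generation and the mean tract length."""
    if mean_tract <= 0:
        raise ValueError("mean tract length must be positive")
    if converted_sites_rate < 0:
        raise ValueError("converted-sites rate must be non-negative")
    return converted_sites_rate / mean_tract


# ---------------------------------------------------------------------------
# state-space construction (cached per migration direction and kmax)
# ---------------------------------------------------------------------------

def _lineage_class(ij):
    return _CLASS[ij]


def _canon(cfg):
    return tuple(sorted(cfg))


def _enumerate_configs(mig_deme):
    """BFS over reachable lineage configurations.

    A configuration is a sorted tuple of lineages ``(i, j, deme)``; demes are
    0 (A) and 1 (B).  ``mig_deme`` is the deme whose lineages can jump to the
    other deme backwards in time (None for DIV).  Configurations with a
    single lineage are terminal and excluded (they map to 'done').
    """
    init = _canon([(1, 0, 0), (1, 0, 0), (0, 1, 1), (0, 1, 1)])
    seen = {init}
    todo = [init]
    while todo:
        cfg = todo.pop()
        for nxt in _neighbours(cfg, mig_deme):
            if len(nxt) >= 2 and nxt not in seen:
                seen.add(nxt)
                todo.append(nxt)
    return sorted(seen)


def _neighbours(cfg, mig_deme):
    out = []
    n = len(cfg)
    for a, b in itertools.combinations(range(n), 2):
        ia, ja, da = cfg[a]
        ib, jb, db = cfg[b]
        if da == db:
            rest = [cfg[k] for k in range(n) if k not in (a, b)]
            out.append(_canon(rest + [(ia + ib, ja + jb, da)]))
    if mig_deme is not None:
        for a in range(n):
            i, j, d = cfg[a]
            if d == mig_deme:
                rest = [cfg[k] for k in range(n) if k != a]
                out.append(_canon(rest + [(i, j, 1 - d)]))
    return out


def _enumerate_configs_onedeme():
    init = _canon([(1, 0, 0), (1, 0, 0), (0, 1, 0), (0, 1, 0)])
    seen = {init}
    todo = [init]
    while todo:
        cfg = todo.pop()
        for nxt in _neighbours(cfg, None):
            if len(nxt) >= 2 and nxt not in seen:
                seen.add(nxt)
                todo.append(nxt)
    return sorted(seen)


def _config_matrices(cfgs, mig_deme):
    """Per-event-class generator skeletons over configs + terminal 'done' row.

    Returns (C0, C1, MIG, V): coalescence-pair matrices per deme, migration
    matrix, and the (n_cfg+1, 4) mutation-class multiplicity array.  Each
    matrix carries its negative diagonal, so multiplying by a rate gives a
    proper sub-generator.
    """
    idx = {c: k for k, c in enumerate(cfgs)}
    n = len(cfgs) + 1  # final row = 'done' (single lineage, absorbing)
    done = n - 1
    mats = {0: {}, 1: {}, "mig": {}}

    def add(which, r, c, w):
        d = mats[which]
        d[(r, c)] = d.get((r, c), 0.0) + w
        d[(r, r)] = d.get((r, r), 0.0) - w

    for k, cfg in enumerate(cfgs):
        nl = len(cfg)
        for a, b in itertools.combinations(range(nl), 2):
            ia, ja, da = cfg[a]
            ib, jb, db = cfg[b]
            if da == db:
                rest = [cfg[x] for x in range(nl) if x not in (a, b)]
                nxt = _canon(rest + [(ia + ib, ja + jb, da)])
                tgt = done if len(nxt) == 1 else idx[nxt]
                add(da, k, tgt, 1.0)
        if mig_deme is not None:
            for a in range(nl):
                i, j, d = cfg[a]
                if d == mig_deme:
                    rest = [cfg[x] for x in range(nl) if x != a]
                    nxt = _canon(rest + [(i, j, 1 - d)])
                    add("mig", k, idx[nxt], 1.0)

    def build(d):
        if not d:
            return sp.csr_matrix((n, n))
        rows, cols, vals = zip(*[(r, c, v) for (r, c), v in d.items()])
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    V = np.zeros((n, 4))
    for k, cfg in enumerate(cfgs):
        for i, j, _ in cfg:
            cl = _lineage_class((i, j))
            if cl >= 0:
                V[k, cl] += 1.0
    return build(mats[0]), build(mats[1]), build(mats["mig"]), V


def _count_matrices(kmax):
    """Count-state shift generators.

    Count states are tuples over {0..kmax, R} per type (R = kmax+1 is the
    residual class).  ``U[k]`` increments type ``k`` (kmax -> R) and carries
    the matching negative diagonal; in R further type-``k`` mutations leave
    the state unchanged (no event, no rate).
    """
    K = kmax + 2
    states = list(itertools.product(range(K), repeat=4))
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    mats = []
    for k in range(4):
        rows, cols, vals = [], [], []
        for s in states:
            if s[k] <= kmax:
                t = list(s)
                t[k] = s[k] + 1
                r = idx[s]
                rows += [r, r]
                cols += [idx[tuple(t)], r]
                vals += [1.0, -1.0]
        mats.append(sp.csr_matrix((vals, (rows, cols)), shape=(n, n)))
    return states, mats


class _Structure:
    """Precomputed (transposed) generator skeletons for one model topology."""

    def __init__(self, mig_deme, kmax):
        self.kmax = kmax
        self.cfgs1 = _enumerate_configs(mig_deme)
        self.cfgs2 = _enumerate_configs_onedeme()
        self.cnt_states, U = _count_matrices(kmax)
        self.n_cnt = len(self.cnt_states)
        C0, C1, MIG, V1 = _config_matrices(self.cfgs1, mig_deme)
        A0, _, _, V2 = _config_matrices(self.cfgs2, None)
        I = sp.identity(self.n_cnt, format="csr")

        def lift(C, V):
            base = sp.kron(C, I, format="csr")
            mut = sum(
                sp.kron(sp.diags(V[:, k]), U[k], format="csr") for k in range(4)
            )
            return base.T.tocsr(), mut.T.tocsr()

        self.K_c0, self.K_mut1 = lift(C0, V1)
        self.K_c1 = sp.kron(C1, I, format="csr").T.tocsr()
        self.K_mig = sp.kron(MIG, I, format="csr").T.tocsr()
        # ancestral phase is solved per count level with small dense blocks
        self.A2 = A0.toarray()
        self.V2 = V2
        K = kmax + 2
        states = np.array(list(itertools.product(range(K), repeat=4)))
        sums = states.sum(axis=1)
        self.levels = []
        for s in range(int(sums.max()) + 1):
            idx = np.nonzero(sums == s)[0]
            if not len(idx):
                continue
            sub = states[idx]
            has = [np.nonzero(sub[:, k] > 0)[0] for k in range(4)]
            patterns = [tuple(bool(v) for v in row) for row in (sub <= kmax)]
            groups = []
            for pat in sorted(set(patterns)):
                rows = np.array([i for i, p in enumerate(patterns) if p == pat])
                groups.append((pat, rows))
            self.levels.append({"idx": idx, "has": has, "groups": groups})

        # projection phase1 -> phase2 state indices
        idx2 = {c: k for k, c in enumerate(self.cfgs2)}
        n1, n2 = len(self.cfgs1) + 1, len(self.cfgs2) + 1
        proj = np.empty(n1, dtype=np.int64)
        for k, cfg in enumerate(self.cfgs1):
            proj[k] = idx2[_canon([(i, j, 0) for i, j, _ in cfg])]
        proj[n1 - 1] = n2 - 1
        self.proj = proj
        self.n1, self.n2 = n1, n2
        init = _canon([(1, 0, 0), (1, 0, 0), (0, 1, 1), (0, 1, 1)])
        self.init1 = self.cfgs1.index(init)
        self.init2 = idx2[_canon([(1, 0, 0), (1, 0, 0), (0, 1, 0), (0, 1, 0)])]


_STRUCTURES: dict = {}


def _structure(mig_deme, kmax) -> _Structure:
    key = (mig_deme, kmax)
    if key not in _STRUCTURES:
        _STRUCTURES[key] = _Structure(mig_deme, kmax)
    return _STRUCTURES[key]


def _expv_uniformized(QT, v, t, tol=1e-13, max_steps=20_000):
    """``exp(QT * t) @ v`` for a (transposed) generator by uniformization.

    Cheaper than ``expm_multiply`` for the modest ``||Q|| * t`` regimes the
    optimiser visits; falls back to scipy's routine when the Poisson series
    would need too many terms (stiff corners of the parameter space).
    """
    lam_max = float(-QT.diagonal().min())
    a = lam_max * t
    if a == 0.0:
        return v.copy()
    n_steps = int(a + 12.0 * np.sqrt(a) + 25.0)
    if n_steps > max_steps:
        return expm_multiply(QT * t, v)
    PT = QT * (1.0 / lam_max)
    PT = PT + sp.identity(QT.shape[0], format="csr")
    # Poisson(a) weights accumulated in a numerically safe recursion
    log_w = -a  # log weight of term 0
    out = np.exp(log_w) * v
    x = v
    for k in range(1, n_steps + 1):
        x = PT @ x
        log_w += np.log(a / k)
        if log_w > -745.0:  # below exp underflow there is nothing to add
            out += np.exp(log_w) * x
        if k > a and log_w < np.log(tol):
            break
    return out


@dataclass
class ConfigProbabilityTable:
    """P(mutation configuration) truncated at ``kmax`` per type.

    ``probs`` has shape ``(kmax+2,)*4`` indexed (hetA, hetB, hetAB, fixed);
    index ``kmax+1`` is the residual (count > kmax) class, so the table sums
    to 1.
    """

    probs: np.ndarray
    kmax: int
    block_length: int
    mu: float
    params: DemographicParams

    def total(self) -> float:
        return float(self.probs.sum())


def bsfs_probabilities(
    params: DemographicParams,
    kmax: int = 2,
    block_length: int = 64,
    mu: float = MU_DEFAULT,
) -> ConfigProbabilityTable:
    """Exact blockwise mutation-configuration probabilities.

    Two-phase matrix-exponential computation over the count-augmented
    structured coalescent (see module docstring).
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if block_length <= 0 or mu < 0:
        raise ValueError("invalid block length or mutation rate")
    lam = mu * block_length  # mutation rate per lineage per generation per block
    if params.model == "DIV" or params.m == 0:
        mig_deme, mig_rate = None, 0.0
    elif params.model == "IM_AB":
        # forwards A->B migration: backwards, lineages in B jump to A
        mig_deme, mig_rate = 1, params.m
    else:  # IM_BA
        mig_deme, mig_rate = 0, params.m
    st = _structure(mig_deme, kmax)
    ncnt = st.n_cnt

    v = np.zeros(st.n1 * ncnt)
    v[st.init1 * ncnt] = 1.0

    if params.t > 0:
        Q1T = (
            (0.5 / params.ne_a) * st.K_c0
            + (0.5 / params.ne_b) * st.K_c1
            + lam * st.K_mut1
        )
        if mig_rate > 0:
            Q1T = Q1T + mig_rate * st.K_mig
        v = _expv_uniformized(Q1T, v, params.t)

    # project onto single-deme phase-2 space
    v2 = np.zeros((st.n2, ncnt))
    v1 = v.reshape(st.n1, ncnt)
    for k in range(st.n1):
        v2[st.proj[k]] += v1[k]

    # absorb in the ancestral phase: the count-augmented system is block
    # lower-triangular in the (monotone) count levels, so solve one small
    # dense config-system per count state in lexicographic order
    K = kmax + 2
    n_c = st.n2 - 1
    coal = 0.5 / params.ne_anc
    A = coal * st.A2  # (n_c+1)^2, row = from, includes -diag
    AT_tr = A[:n_c, :n_c].T
    to_done = A[:n_c, n_c]
    V = st.V2[:n_c]
    mut_out = lam * V  # (n_c, 4) outflow per active mutation class
    w = v2[:n_c].T  # (ncnt, n_c)
    done = v2[n_c].copy()
    y = np.empty((ncnt, n_c))
    # precompute the 16 inverses (one per residual pattern)
    inv_by_pattern = {}
    for active in itertools.product((True, False), repeat=4):
        sel = [k for k in range(4) if active[k]]
        M = -AT_tr + np.diag(mut_out[:, sel].sum(axis=1))
        inv_by_pattern[active] = np.linalg.inv(M)
    for level in st.levels:
        idx = level["idx"]
        rhs = w[idx].copy()
        for k in range(4):
            has = level["has"][k]
            if len(has):
                rhs[has] += lam * V[:, k] * y[idx[has] - K ** (3 - k)]
        for active, rows in level["groups"]:
            y[idx[rows]] = rhs[rows] @ inv_by_pattern[active].T
        done[idx] += y[idx] @ to_done
    probs = done.reshape((K, K, K, K))
    return ConfigProbabilityTable(probs, kmax, block_length, mu, params)


def bsfs_probabilities_mc(
    params: DemographicParams,
    kmax: int = 2,
    block_length: int = 64,
    mu: float = MU_DEFAULT,
    n_genealogies: int = 100_000,
    seed: int = 1,
    return_se: bool = False,
):
    """Monte-Carlo estimate of the same table from simulated genealogies.

    Samples structured-coalescent genealogies (Gillespie algorithm over the
    4-lineage chain), then averages the exact product of Poisson terms given
    the class branch lengths (Rao-Blackwellised, so no mutation-sampling
    noise).  Independent implementation used as the oracle for
    :func:`bsfs_probabilities`.
    """
    from . import mc

    L = mc.sample_class_lengths(params, n_genealogies, seed)
    lam = mu * block_length
    tab, se = mc.poisson_table(L, lam, kmax)
    table = ConfigProbabilityTable(tab, kmax, block_length, mu, params)
    if return_se:
        return table, se
    return table


# ---------------------------------------------------------------------------
# composite likelihood and fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: DemographicParams
    lnCL: float
    converged: bool
    n_blocks: int
    kmax: int
    block_length: int
    mu: float
    trace: list = field(default_factory=list, repr=False)

    def scaled(self) -> dict:
        return to_scaled(self.params)


def composite_loglik(tally, table: ConfigProbabilityTable) -> float:
    """``lnCL = sum_config count * ln P(config)``.

    ``tally`` is a :class:`~invcoal.blocks.BSFSTally` (or anything with a
    matching ``counts`` array of shape ``(kmax+2,)*4``).  Returns ``-inf``
    when a configuration with support has zero probability.
    """
    counts = np.asarray(tally.counts, dtype=float)
    if counts.shape != table.probs.shape:
        raise ValueError(
            f"tally shape {counts.shape} does not match table {table.probs.shape}"
        )
    p = table.probs
    mask = counts > 0
    if np.any(p[mask] <= 0):
        return -np.inf
    return float(np.sum(counts[mask] * np.log(p[mask])))


_BOUNDS_LOG = {
    "ne": (np.log(1e3), np.log(5e7)),
    "t": (np.log(1e3), np.log(5e7)),
    "m": (np.log(1e-12), np.log(1e-5)),
}


def _moment_start(tally, mu, ell, model):
    """Method-of-moments start: sizes from heterozygosities, t from d_xy."""
    c = np.asarray(tally.counts, dtype=float)
    kmax = c.shape[0] - 2
    n = c.sum()
    vals = np.arange(c.shape[0], dtype=float)
    vals[-1] = kmax + 1  # residual scored at its minimum count
    mA = float(np.einsum("abcd,a->", c, vals) / n)
    mB = float(np.einsum("abcd,b->", c, vals) / n)
    mAB = float(np.einsum("abcd,c->", c, vals) / n)
    mF = float(np.einsum("abcd,d->", c, vals) / n)
    piA = max((mA + mAB) / ell, 1e-6)
    piB = max((mB + mAB) / ell, 1e-6)
    dxy = max((0.5 * (mA + mB + mAB) + mF) / ell, 1e-6)
    ne_a = piA / (4 * mu)
    ne_b = piB / (4 * mu)
    ne_anc = 0.5 * (ne_a + ne_b)
    t0 = max(dxy / (2 * mu) - 2 * ne_anc, 0.05 * dxy / (2 * mu))
    x = [np.log(ne_a), np.log(ne_b), np.log(ne_anc), np.log(t0)]
    if model != "DIV":
        x.append(np.log(max(0.01 / (2 * ne_b), 1e-11)))
    return np.array(x)


_PARAM_ORDER = ("ne_a", "ne_b", "ne_anc", "t", "m")


def fit_model(
    tally,
    model: str = "IM_AB",
    mu: float = MU_DEFAULT,
    n_starts: int = 5,
    seed: int = 0,
    maxfev: int = 2000,
    fatol: float = 1e-4,
    bounds: dict | None = None,
    fixed: dict | None = None,
    start_params: DemographicParams | None = None,
) -> FitResult:
    """Maximise the composite likelihood by multi-start Nelder-Mead search.

    Parameters are optimised on the log scale (DIV: 4 free; IM: 5 free).
    The first start is a method-of-moments guess (or ``start_params`` when
    given); the remaining ``n_starts - 1`` are drawn log-uniformly within
    bounds from ``seed``.  ``fixed`` pins a subset of parameters at given
    absolute values (profile fits; also used by the parametric bootstrap).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if getattr(tally, "n_blocks", None) in (0, None) and np.asarray(tally.counts).sum() == 0:
        raise ValueError("empty tally")
    ell = tally.block_length
    kmax = tally.kmax
    blog = dict(_BOUNDS_LOG)
    if bounds:
        blog.update({k: (np.log(v[0]), np.log(v[1])) for k, v in bounds.items()})
    names = ["ne_a", "ne_b", "ne_anc", "t"] + (["m"] if model != "DIV" else [])
    fixed = dict(fixed or {})
    free = [n for n in names if n not in fixed]
    if not free:
        raise ValueError("no free parameters")

    def _bound(n):
        return blog["m"] if n == "m" else (blog["t"] if n == "t" else blog["ne"])

    lo = np.array([_bound(n)[0] for n in free])
    hi = np.array([_bound(n)[1] for n in free])

    def build_params(x):
        vals = {n: float(fixed[n]) for n in fixed if n in names}
        for n, xi in zip(free, x):
            vals[n] = float(np.exp(xi))
        vals.setdefault("m", 0.0)
        return DemographicParams(
            vals["ne_a"], vals["ne_b"], vals["ne_anc"], vals["t"], vals["m"], model
        )

    trace = []

    def objective(x):
        try:
            p = build_params(np.clip(x, lo, hi))
            tab = bsfs_probabilities(p, kmax=kmax, block_length=ell, mu=mu)
            ll = composite_loglik(tally, tab)
        except (ValueError, FloatingPointError, RuntimeError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        trace.append((x.copy(), ll))
        return -ll

    rng = np.random.default_rng(seed)
    if start_params is not None:
        x0 = np.array([np.log(max(getattr(start_params, n), 1e-300)) for n in free])
    else:
        full = _moment_start(tally, mu, ell, model)
        x0 = np.array([full[names.index(n)] for n in free])
    starts = [np.clip(x0, lo, hi)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.uniform(lo, hi))

    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxfev": maxfev, "fatol": fatol, "xatol": 1e-4, "adaptive": True},
        )
        if best is None or res.fun < best.fun - 1e-12 or (
            abs(res.fun - best.fun) <= 1e-12
            and tuple(res.x) < tuple(best.x)  # deterministic tie-break
        ):
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("all optimizer starts failed")
    params = build_params(np.clip(best.x, lo, hi))
    return FitResult(
        params=params,
        lnCL=-float(best.fun),
        converged=bool(best.success),
        n_blocks=int(np.asarray(tally.counts).sum()),
        kmax=kmax,
        block_length=ell,
        mu=mu,
        trace=trace,
    )


def compare_models(fit_a: FitResult, fit_b: FitResult) -> dict:
    """Difference in composite-likelihood support between two fits of the
    same tally; significance is deferred to the parametric bootstrap."""
    if (fit_a.n_blocks, fit_a.kmax, fit_a.block_length) != (
        fit_b.n_blocks,
        fit_b.kmax,
        fit_b.block_length,
    ):
        raise ValueError("fits compare different tallies")
    delta = fit_a.lnCL - fit_b.lnCL
    return {
        "delta_lnCL": delta,
        "best": fit_a.params.model if delta >= 0 else fit_b.params.model,
    }
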