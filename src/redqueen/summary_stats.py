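"""Closed-form and population-averaged summary statistics.

For a diploid genotype, the probability ``q`` that a DSB falls at a
symmetrically bound site is a ratio of occupancy moments over the genotype's
target sites; fertility is the probability of at least one symmetric DSB,
``w = 1 - exp(-d q)`` (Poisson number of symmetric DSBs with mean ``d q``).
Haplo-insufficiency ``sigma`` compares the fertility of a homozygote (dosage
``c_hom``) with that of a hemizygote (one gene copy, dosage 1).

Moments ``<x^k>`` are means over an allele's ``h`` sites with inactive sites
contributing zero occupancy, computed from the realized per-site affinities
the simulator tracks (not by quadrature over the exponential law).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_model import AffinityDistribution, Population
from .meiosis_kernel import occupancy

__all__ = [
    "AlleleStats", "MomentSet", "moments",
    "diversity", "q_hom", "q_het", "fertility", "haplo_insufficiency",
    "sigma0", "allele_background_average", "selection_on_new_alleles",
]


@dataclass
class AlleleStats:
    """Per-allele population statistics at one generation."""

    allele_id: int
    f: float            # frequency over 2N haplotypes
    theta: float        # mean fraction of still-active sites over copies
    mean_affinity_active: float
    q: float            # carrier-averaged symmetric-binding probability
    w: float            # carrier-averaged fertility


@dataclass
class MomentSet:
    """Means <x>, <x^2>, <x^3> of site occupancy over an allele's sites."""

    m1: float
    m2: float
    m3: float

    @property
    def sterile(self) -> bool:
        return self.m1 == 0.0


def moments(affinities: np.ndarray, c: float = 1.0,
            active: np.ndarray | None = None) -> MomentSet:
    """Occupancy moments at dosage ``c``; inactive sites count as x = 0."""
    x = occupancy(np.asarray(affinities, dtype=float), c)
    h = len(x)
    if h == 0:
        raise ValueError("empty affinity array")
    if active is not None:
        x = x * np.asarray(active, dtype=float)
    return MomentSet(float(np.sum(x) / h), float(np.sum(x ** 2) / h),
                     float(np.sum(x ** 3) / h))


def diversity(frequencies) -> float:
    """Effective number of alleles D = 1 / sum(f_i^2) (inverse homozygosity)."""
    if isinstance(frequencies, dict):
        f = np.asarray(list(frequencies.values()), dtype=float)
    else:
        f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency vector")
    if not np.isclose(f.sum(), 1.0, atol=1e-8):
        raise ValueError("frequencies must sum to 1")
    return float(1.0 / np.sum(f ** 2))


def q_hom(m: MomentSet) -> float:
    """Symmetric-binding probability of a homozygote, (2<x^2> - <x^3>)/<x>.

    A fully eroded genotype (<x> = 0) cannot bind at all: q is defined as 0
    (the ``sterile`` flag lives on the MomentSet).
    """
    if m.sterile:
        return 0.0
    return (2.0 * m.m2 - m.m3) / m.m1


def q_het(mi: MomentSet, mj: MomentSet) -> float:
    """Symmetric-binding probability of a heterozygote (both at c = 1)."""
    denom = mi.m1 + mj.m1
    if denom == 0.0:
        return 0.0
    return (2.0 * mi.m2 - mi.m3 + 2.0 * mj.m2 - mj.m3) / denom


def fertility(q: float, d: float) -> float:
    """Meiosis success probability w = 1 - exp(-d q)."""
    if np.any(np.asarray(q) < 0) or np.any(np.asarray(q) > 1):
        raise ValueError("q must be in [0, 1]")
    if not d > 0:
        raise ValueError("d must be > 0")
    return -np.expm1(-d * np.asarray(q)) if np.ndim(q) else float(-np.expm1(-d * q))


def haplo_insufficiency(w_hom: float, w_hemi: float) -> float:
    """Relative fertility difference sigma = (w_hom - w_hemi) / w_hemi."""
    if w_hemi == 0.0:
        raise ValueError("sigma undefined for a sterile hemizygote (w_hemi = 0)")
    return (w_hom - w_hemi) / w_hemi


def _fresh_allele_distribution(config) -> AffinityDistribution:
    """Affinity law for hypothetical fresh alleles, mirroring the config."""
    return AffinityDistribution(config.mean_affinity,
                                stratified=getattr(config, "stratified_affinities", True))


def sigma0(config, n_rep: int = 100, rng: np.random.Generator | None = None) -> float:
    """Mean haplo-insufficiency of fresh alleles.

    Draws ``n_rep`` new alleles (``config.h`` affinities each, exponential
    with mean ``config.mean_affinity``), computes each allele's fertility as
    a homozygote (dosage ``config.c_hom``) and as a hemizygote (dosage 1) at
    zero erosion, and returns the mean relative difference. ``config`` only
    needs attributes ``mean_affinity``, ``h``, ``d`` and ``c_hom``.
    """
    rng = np.random.default_rng() if rng is None else rng
    dist = _fresh_allele_distribution(config)
    sig = np.empty(n_rep)
    for r in range(n_rep):
        y = dist.sample(config.h, rng)
        w_hom = fertility(q_hom(moments(y, config.c_hom)), config.d)
        w_hemi = fertility(q_hom(moments(y, 1.0)), config.d)
        sig[r] = haplo_insufficiency(w_hom, w_hemi)
    return float(sig.mean())


# ---------------------------------------------------------- population level


def _genotype_qw(pop: Population, i: int, d: float, c_hom: float) -> tuple[float, float]:
    rA = int(pop.hap_allele[2 * i])
    rB = int(pop.hap_allele[2 * i + 1])
    aA = pop.registry[int(pop.allele_ids[rA])]
    aB = pop.registry[int(pop.allele_ids[rB])]
    stA = pop.block_state(2 * i, aA)
    stB = pop.block_state(2 * i + 1, aB)
    if rA == rB:
        mA = moments(aA.affinities, c_hom, active=stA)
        mB = moments(aB.affinities, c_hom, active=stB)
        m = MomentSet((mA.m1 + mB.m1) / 2, (mA.m2 + mB.m2) / 2, (mA.m3 + mB.m3) / 2)
        q = q_hom(m)
    else:
        q = q_het(moments(aA.affinities, 1.0, active=stA),
                  moments(aB.affinities, 1.0, active=stB))
    return q, fertility(q, d)


def allele_background_average(pop: Population, allele_id: int, stat: str,
                              d: float, c_hom: float = 1.0) -> float:
    """Carrier-averaged statistic for one allele.

    Averages the per-genotype ``q`` or ``w`` over all diploid carriers, with
    weight 1 for heterozygotes and weight 2 for homozygotes (one unit per
    carried copy).
    """
    if stat not in ("q", "w"):
        raise ValueError("stat must be 'q' or 'w'")
    if allele_id not in pop.registry:
        raise KeyError(f"allele {allele_id} not in population")
    row = pop.registry[allele_id].row
    total = 0.0
    weight = 0.0
    for i in range(pop.N):
        wgt = int(pop.hap_allele[2 * i] == row) + int(pop.hap_allele[2 * i + 1] == row)
        if wgt == 0:
            continue
        q, w = _genotype_qw(pop, i, d, c_hom)
        total += wgt * (q if stat == "q" else w)
        weight += wgt
    if weight == 0:
        raise KeyError(f"allele {allele_id} has no carriers")
    return total / weight


def selection_on_new_alleles(pop: Population, config,
                             rng: np.random.Generator,
                             n_probes: int = 10) -> float:
    """Snapshot selection coefficient s0 on hypothetical new alleles.

    Probe alleles are created on the fly (never inserted), combined as
    heterozygotes with every haplotype segregating in the population; s0 is
    the mean log fitness of the probes minus the population mean log fitness.
    Fitness is the per-parent-draw meiosis success ``1 - (1 - w)^n_mei``.
    ``config`` needs ``mean_affinity``, ``h``, ``d``, ``c_hom``, ``n_mei``.
    """
    d, c_hom = config.d, config.c_hom
    n_mei = getattr(config, "n_mei", 1)

    def log_fitness(w):
        ww = 1.0 - (1.0 - np.asarray(w)) ** n_mei
        return np.log(np.maximum(ww, 1e-300))

    # per-haplotype realized moments at c = 1
    hap_m = []
    for idx in range(2 * pop.N):
        a = pop.registry[int(pop.allele_ids[pop.hap_allele[idx]])]
        hap_m.append(moments(a.affinities, 1.0, active=pop.block_state(idx, a)))
    dist = _fresh_allele_distribution(config)
    probe_logw = np.empty(n_probes)
    for p in range(n_probes):
        y = dist.sample(config.h, rng)
        mp = moments(y, 1.0)
        ws = np.array([fertility(q_het(mp, m), d) for m in hap_m])
        probe_logw[p] = log_fitness(ws).mean()
    pop_logw = np.array([log_fitness(_genotype_qw(pop, i, d, c_hom)[1])
                         for i in range(pop.N)])
    return float(probe_logw.mean() - pop_logw.mean())
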