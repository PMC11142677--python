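"""One meiosis, step by step.

Binding follows the chemical equilibrium of PRDM9 with its target sites:
a site of rescaled affinity ``y`` bound by an allele at dosage multiplier
``c`` is occupied with probability ``x = c y / (1 + c y)`` (PRDM9 is assumed
non-limiting, so there is no competition between sites). DSBs are induced at
bound sites with probability ``min(1, d/k)`` where ``k`` is the number of
bound site instances over the four chromatids, so that about ``d`` DSBs are
made per meiosis. In the symmetry-required mode, meiosis succeeds only if at
least one DSB falls at a site that is also bound on at least one chromatid
of the other homolog; one such symmetric DSB becomes the single CO. In the
control mode (no symmetry requirement) any DSB suffices and the CO is drawn
uniformly among all DSBs. All DSBs are repaired by copying the homolog's
site state at the broken locus, which implements biased gene conversion in
favor of inactive site variants (the hotspot conversion paradox).

``bind_chromatids``/``place_dsbs``/``find_symmetric_dsbs`` are plain-NumPy
reference implementations of the individual steps, used by tests and trace
inspection; ``resolve_meiosis`` runs the same fused compiled kernel as the
generation loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .genome_model import Allele, Haplotype, Individual

SYMMETRY_REQUIRED = "symmetry_required"
CONTROL_NO_SYMMETRY = "control_no_symmetry"
MODES = (SYMMETRY_REQUIRED, CONTROL_NO_SYMMETRY)

_FAILURE_NAMES = {
    _kernels.STATUS_NO_BINDING: "no_binding",
    _kernels.STATUS_NO_SYMMETRIC_DSB: "no_symmetric_dsb",
    _kernels.STATUS_NO_DSB: "no_dsb",
}

__all__ = [
    "SYMMETRY_REQUIRED", "CONTROL_NO_SYMMETRY", "MODES",
    "ChromatidState", "MeiosisOutcome",
    "occupancy", "bind_chromatids", "place_dsbs", "find_symmetric_dsbs",
    "resolve_meiosis",
]


def occupancy(y, c: float = 1.0):
    """Equilibrium site occupancy ``x = c y / (1 + c y)``.

    ``c`` is the gene-dosage multiplier (1 for a heterozygote or hemizygote,
    ``c_hom`` for a homozygote). Strictly increasing in both arguments.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("affinity y must be >= 0")
    if not c > 0:
        raise ValueError("dosage multiplier c must be > 0")
    x = c * y / (1.0 + c * y)
    return float(x) if x.ndim == 0 else x


@dataclass
class ChromatidState:
    """One of the four chromatids during a meiosis."""

    parent: str                # "A" or "B"
    sister_index: int          # 0 or 1
    prdm9_allele: int
    bound_loci: set = field(default_factory=set)
    dsb_loci: set = field(default_factory=set)
    inactive_loci: set = field(default_factory=set)


@dataclass
class MeiosisOutcome:
    success: bool
    failure_reason: str | None = None
    co_locus: int | None = None
    gamete: Haplotype | None = None
    n_bound: int = 0
    n_dsb: int = 0
    n_symmetric: int = 0
    trace: dict | None = None


def _carried(individual: Individual, registry: dict[int, Allele]) -> list[Allele]:
    ids = {individual.hap_a.prdm9_allele, individual.hap_b.prdm9_allele}
    return [registry[i] for i in sorted(ids)]


def bind_chromatids(individual: Individual, registry: dict[int, Allele],
                    c_hom: float, rng: np.random.Generator) -> list[ChromatidState]:
    """Reference binding step: Bernoulli(occupancy) per active site instance.

    Only sites of the two carried alleles can be bound (an allele's protein
    is absent unless the genotype carries it); inactive sites never bind.
    """
    alleles = _carried(individual, registry)
    hom = len(alleles) == 1
    chromatids = []
    for parent, hap in (("A", individual.hap_a), ("B", individual.hap_b)):
        for sister in (0, 1):
            ch = ChromatidState(parent=parent, sister_index=sister,
                                prdm9_allele=hap.prdm9_allele,
                                inactive_loci=set(hap.inactive_loci))
            for a in alleles:
                c = c_hom if hom else 1.0
                x = occupancy(a.affinities, c)
                active = ~np.isin(a.loci, list(hap.inactive_loci)) if hap.inactive_loci else np.ones(a.h, bool)
                hit = active & (rng.random(a.h) < x)
                ch.bound_loci.update(int(p) for p in a.loci[hit])
            chromatids.append(ch)
    return chromatids


def place_dsbs(chromatids: list[ChromatidState], d: float,
               rng: np.random.Generator) -> tuple[list[ChromatidState], str | None]:
    """Reference DSB step: each bound instance breaks w.p. min(1, d/k)."""
    k = sum(len(c.bound_loci) for c in chromatids)
    if k == 0:
        return chromatids, "no_binding"
    p = min(1.0, d / k)
    for c in chromatids:
        loci = np.array(sorted(c.bound_loci), dtype=np.int64)
        hit = rng.random(len(loci)) < p
        c.dsb_loci = set(int(x) for x in loci[hit])
    return chromatids, None


def find_symmetric_dsbs(chromatids: list[ChromatidState]) -> set[tuple[int, int]]:
    """DSBs at loci bound on >= 1 chromatid of the *other* parent homolog."""
    out = set()
    for t, c in enumerate(chromatids):
        others = [o for o in chromatids if o.parent != c.parent]
        for locus in c.dsb_loci:
            if any(locus in o.bound_loci for o in others):
                out.add((t, locus))
    return out


def _genotype_arrays(individual: Individual, registry: dict[int, Allele],
                     c_hom: float):
    """Flatten an Individual into the kernel's sorted-column representation."""
    alleles = sorted(registry.values(), key=lambda a: a.allele_id)
    if not alleles:
        raise ValueError("empty allele registry")
    h = alleles[0].h
    if any(a.h != h for a in alleles):
        raise ValueError("all alleles must have the same number of targets h")
    raw_pos = np.concatenate([a.loci for a in alleles])
    raw_aff = np.concatenate([a.affinities for a in alleles])
    order = np.argsort(raw_pos, kind="stable")
    inv = np.empty(len(order), dtype=np.int64)
    inv[order] = np.arange(len(order))
    col_pos = raw_pos[order]
    col_aff = raw_aff[order]
    n_alleles = len(alleles)
    allele_cols = inv.reshape(n_alleles, h)
    rows = {a.allele_id: r for r, a in enumerate(alleles)}
    states = []
    for hap in (individual.hap_a, individual.hap_b):
        st = np.ones(len(col_pos), dtype=np.uint8)
        if hap.inactive_loci:
            st[np.isin(col_pos, list(hap.inactive_loci))] = 0
        states.append(st)
    aff_rows = col_aff[allele_cols]
    cdf_het = np.ascontiguousarray(_kernels.binding_cdf(aff_rows / (1.0 + aff_rows)))
    xh = c_hom * aff_rows / (1.0 + c_hom * aff_rows)
    cdf_hom = np.ascontiguousarray(_kernels.binding_cdf(xh))
    return (states[0], states[1], rows[individual.hap_a.prdm9_allele],
            rows[individual.hap_b.prdm9_allele], h, allele_cols,
            cdf_hom, cdf_het, col_aff, col_pos, rows)


def resolve_meiosis(individual: Individual, registry: dict[int, Allele],
                    mode: str, d: float, c_hom: float,
                    rng: np.random.Generator,
                    prdm9_slot: int | None = None,
                    trace: bool = False) -> MeiosisOutcome:
    """Execute one full meiosis attempt on an individual.

    Runs the same compiled kernel as the simulation loop. Failure is a valid
    outcome (``no_binding``, ``no_symmetric_dsb`` in symmetry-required mode,
    ``no_dsb`` in control mode).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    (stA, stB, rowA, rowB, h, allele_cols, cdf_hom, cdf_het,
     col_aff, col_pos, rows) = _genotype_arrays(individual, registry, c_hom)
    if prdm9_slot is None:
        prdm9_slot = int(col_pos.max()) // 2
    n_cols = len(col_pos)
    out_gamete = np.empty(n_cols, dtype=np.uint8)
    bound_nib = np.empty(2 * h, dtype=np.uint8)
    buf_t = np.empty(8 * h, dtype=np.int64)
    buf_j = np.empty(8 * h, dtype=np.int64)
    buf_sym = np.empty(8 * h, dtype=np.uint8)

    rs = _kernels.new_rng_state(int(rng.integers(2 ** 62)))
    status, k, nd, ns, co_i, t_co, t_partner, t_gam, gam_row = _kernels.attempt_meiosis(
        stA, stB, np.int64(rowA), np.int64(rowB), allele_cols, h,
        cdf_hom.reshape(-1, 5), cdf_het.reshape(-1, 5), col_pos, n_cols,
        np.int64(prdm9_slot), float(d), mode == SYMMETRY_REQUIRED, rs,
        out_gamete, buf_t, buf_j, buf_sym, bound_nib,
        _kernels._POPCOUNT4, _kernels._PATTERNS4, _kernels._NPATTERNS4)

    row2id = {v: kk for kk, v in rows.items()}
    outcome = MeiosisOutcome(success=(status == _kernels.STATUS_OK),
                             failure_reason=_FAILURE_NAMES.get(status),
                             n_bound=int(k), n_dsb=int(nd), n_symmetric=int(ns))
    hom = rowA == rowB

    def _rel_col(j):
        return allele_cols[rowA, j] if j < h else allele_cols[rowB, j - h]

    if outcome.success:
        outcome.co_locus = int(col_pos[_rel_col(int(buf_j[co_i]))])
        inactive = set(int(p) for p in col_pos[out_gamete == 0])
        outcome.gamete = Haplotype(prdm9_allele=row2id[int(gam_row)],
                                   inactive_loci=inactive)
    if trace:
        n_rel = h if hom else 2 * h
        bound_sets = [
            sorted(int(col_pos[_rel_col(j)]) for j in range(n_rel)
                   if bound_nib[j] & (1 << t))
            for t in range(4)
        ]
        dsbs = [(int(buf_t[i]), int(col_pos[_rel_col(int(buf_j[i]))]), bool(buf_sym[i]))
                for i in range(nd)]
        outcome.trace = {
            "k": int(k),
            "bound_loci": bound_sets,
            "dsbs": [{"chromatid": t, "locus": p, "symmetric": s} for t, p, s in dsbs],
            "co_locus": outcome.co_locus,
            "co_chromatids": [int(t_co), int(t_partner)] if outcome.success else None,
            "gamete_chromatid": int(t_gam) if outcome.success else None,
            "failure_reason": outcome.failure_reason,
        }
    return outcome
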