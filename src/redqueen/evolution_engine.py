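"""Wright-Fisher generation loop driving the Red Queen.

Each generation: (1) the PRDM9 locus mutates with probability ``u`` per gene
copy, creating fresh alleles with new target sets; (2) every active target
site instance mutates to the inactive state with probability ``v`` per
haploid copy; (3) exactly N offspring are produced, each from two gametes
obtained independently by drawing a parent uniformly (with replacement) and
attempting up to ``n_mei`` meioses on it, redrawing the parent if all
attempts fail. Generations are non-overlapping.

Summary statistics (PRDM9 diversity D, mean active-site fraction theta-bar,
carrier-averaged q and w, haplo-insufficiency, the selection coefficient s0
on probe alleles) are recorded along the trajectory and averaged over the
post-burn-in generations to characterize the equilibrium regime.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .genome_model import (AffinityDistribution, Haplotype, Individual,
                           Population, mutate_prdm9, mutate_targets)
from .meiosis_kernel import MODES, SYMMETRY_REQUIRED

__all__ = ["SimulationConfig", "SimulationResult", "make_offspring",
           "step_generation", "run"]


@dataclass
class SimulationConfig:
    """Input parameters of one simulation.

    ``rescale`` records the scaling factor lambda already applied relative
    to the nominal population (N divided by, u and v multiplied by lambda);
    it only affects reporting of population-scaled quantities such as 4Ns0.
    """

    N: int
    u: float
    v: float
    h: int
    d: float
    mean_affinity: float
    generations: int
    burn_in: int = 0
    c_hom: float = 1.0
    n_mei: int = 1
    mode: str = SYMMETRY_REQUIRED
    seed: int = 0
    L: int | None = None
    prdm9_slot: int | None = None
    rescale: float = 1.0
    stats_interval: int = 10
    theta_interval: int = 1
    s0_interval: int = 100
    s0_probes: int = 10
    invasion_threshold: float = 0.1
    stratified_affinities: bool = True
    record_trajectory: bool = True
    max_parent_draws: int = 1_000_000

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        for name in ("u", "v"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not (self.generations >= self.burn_in >= 0):
            raise ValueError("need generations >= burn_in >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 1.0 <= self.c_hom <= 2.0:
            raise ValueError("c_hom must be in [1, 2]")
        if not 1 <= self.n_mei <= 5:
            raise ValueError("n_mei must be in 1..5")
        if self.d <= 0 or self.h <= 0 or self.mean_affinity <= 0:
            raise ValueError("d, h and mean_affinity must be positive")

    def affinity_distribution(self) -> AffinityDistribution:
        return AffinityDistribution(self.mean_affinity,
                                    stratified=self.stratified_affinities)

    def rescaled(self, lam: float) -> "SimulationConfig":
        """Speed rescaling: N / lam, u and v * lam (4Nu, 4Nv invariant)."""
        N = self.N / lam
        if abs(N - round(N)) > 1e-9:
            raise ValueError("N must stay an integer under rescaling")
        return dataclasses.replace(self, N=int(round(N)), u=self.u * lam,
                                   v=self.v * lam, rescale=self.rescale * lam)


@dataclass
class SimulationResult:
    config: SimulationConfig
    scalars: pd.DataFrame          # per-generation population scalars
    trajectory: pd.DataFrame | None  # per-allele records at stats intervals
    summary: dict                  # post-burn-in equilibrium means
    population: Population        # final state


class _Engine:
    """Scratch buffers and occupancy/CDF caches shared across generations."""

    def __init__(self, pop: Population, config: SimulationConfig,
                 rng_state: np.ndarray | None = None):
        self.cfg = config
        self.rng_state = rng_state if rng_state is not None else _kernels.new_rng_state(config.seed)
        self._next_state = np.zeros_like(pop.hap_state)
        self._next_allele = np.zeros_like(pop.hap_allele)
        self._xver = -1
        self._x = None
        self._epoch = -1
        self._cdf_rows = 0
        self._cdf_hom = np.zeros((0, pop.h, 5))
        self._cdf_het = np.zeros((0, pop.h, 5))

    def _cdf_tables(self, pop: Population):
        """Per-allele binding CDF tables, extended incrementally on births."""
        if pop.layout_epoch != self._epoch:
            self._epoch = pop.layout_epoch
            self._cdf_rows = 0
            self._cdf_hom = np.zeros((pop._row_cap, pop.h, 5))
            self._cdf_het = np.zeros((pop._row_cap, pop.h, 5))
        elif pop.n_rows > self._cdf_hom.shape[0]:
            grow = np.zeros((pop._row_cap, pop.h, 5))
            grow[: self._cdf_rows] = self._cdf_hom[: self._cdf_rows]
            self._cdf_hom, grow = grow, np.zeros((pop._row_cap, pop.h, 5))
            grow[: self._cdf_rows] = self._cdf_het[: self._cdf_rows]
            self._cdf_het = grow
        if pop.n_rows > self._cdf_rows:
            sl = slice(self._cdf_rows, pop.n_rows)
            aff = pop.col_aff[pop.allele_cols[sl]]
            ch = self.cfg.c_hom
            self._cdf_het[sl] = _kernels.binding_cdf(aff / (1.0 + aff))
            self._cdf_hom[sl] = _kernels.binding_cdf(ch * aff / (1.0 + ch * aff))
            self._cdf_rows = pop.n_rows
        return self._cdf_hom, self._cdf_het

    def x_arrays(self, pop: Population):
        if pop.version != self._xver:
            aff = pop.col_aff[: pop.n_cols]
            x1 = aff / (1.0 + aff)
            ch = self.cfg.c_hom
            xh = ch * aff / (1.0 + ch * aff)
            cdf_hom, cdf_het = self._cdf_tables(pop)
            self._x = (x1, x1 * x1, x1 * x1 * x1, xh, xh * xh, xh * xh * xh,
                       cdf_hom.reshape(-1, 5), cdf_het.reshape(-1, 5))
            self._xver = pop.version
        return self._x

    def step(self, pop: Population, rng: np.random.Generator) -> None:
        cfg = self.cfg
        mutate_prdm9(pop, cfg.u, rng)
        mutate_targets(pop, cfg.v, rng)
        if self._next_state.shape != pop.hap_state.shape:
            self._next_state = np.zeros_like(pop.hap_state)
        x = self.x_arrays(pop)
        ok = _kernels.fill_next_generation(
            pop.hap_state, pop.hap_allele, self._next_state, self._next_allele,
            pop.n_cols, pop.h, pop.allele_cols, x[6], x[7], pop.col_pos,
            pop.sorted_prefix, np.int64(pop.prdm9_pos), float(cfg.d),
            cfg.mode == SYMMETRY_REQUIRED, cfg.n_mei, cfg.max_parent_draws,
            self.rng_state)
        if ok < 0:
            raise RuntimeError(
                f"generation {pop.generation}: {cfg.max_parent_draws} consecutive "
                "parent draws failed every meiosis; population effectively sterile")
        pop.hap_state, self._next_state = self._next_state, pop.hap_state
        pop.hap_allele, self._next_allele = self._next_allele, pop.hap_allele
        pop.generation += 1
        pop.gc()


def _kernel_state_from(rng: np.random.Generator) -> np.ndarray:
    return _kernels.new_rng_state(int(rng.integers(2 ** 62)))


def make_offspring(pop: Population, config: SimulationConfig,
                   rng: np.random.Generator) -> Individual:
    """Produce one offspring: two independent rejection-sampled gametes."""
    eng = _Engine(pop, config, _kernel_state_from(rng))
    x = eng.x_arrays(pop)
    out = np.empty((2, pop._cap), dtype=np.uint8)
    rows = np.empty(2, dtype=np.int64)
    ok = _kernels.fill_next_generation(
        pop.hap_state, pop.hap_allele, out, rows,
        pop.n_cols, pop.h, pop.allele_cols, x[6], x[7], pop.col_pos,
        pop.sorted_prefix, np.int64(pop.prdm9_pos), float(config.d),
        config.mode == SYMMETRY_REQUIRED, config.n_mei,
        config.max_parent_draws, eng.rng_state)
    if ok < 0:
        raise RuntimeError("population effectively sterile")
    haps = []
    for g in range(2):
        inactive = set(int(p) for p in pop.col_pos[: pop.n_cols][out[g, : pop.n_cols] == 0])
        haps.append(Haplotype(prdm9_allele=int(pop.allele_ids[rows[g]]),
                              inactive_loci=inactive))
    return Individual(haps[0], haps[1])


def step_generation(pop: Population, config: SimulationConfig,
                    rng: np.random.Generator) -> Population:
    """Advance the population by one full generation (in place)."""
    _Engine(pop, config, _kernel_state_from(rng)).step(pop, rng)
    return pop


def _full_stats(pop: Population, cfg: SimulationConfig, x):
    """Per-haplotype block stats -> per-genotype q/w (analytic formulas)."""
    hm = _kernels.hap_block_stats(pop.hap_state, pop.hap_allele,
                                  pop.allele_cols, pop.h,
                                  x[0], x[1], x[2], x[3], x[4], x[5],
                                  pop.col_aff[: pop.n_cols])
    A = hm[0::2]
    B = hm[1::2]
    hom = pop.hap_allele[0::2] == pop.hap_allele[1::2]
    # homozygote: average the two copies' moments at dosage c_hom
    m1 = np.where(hom, 0.5 * (A[:, 4] + B[:, 4]), A[:, 1] + B[:, 1])
    m2 = np.where(hom, 0.5 * (A[:, 5] + B[:, 5]), A[:, 2] + B[:, 2])
    m3 = np.where(hom, 0.5 * (A[:, 6] + B[:, 6]), A[:, 3] + B[:, 3])
    q = np.where(m1 > 0, (2.0 * m2 - m3) / np.where(m1 > 0, m1, 1.0), 0.0)
    w = -np.expm1(-cfg.d * q)
    return hm, q, w


def _sigma_bar(pop: Population, cfg: SimulationConfig, hm: np.ndarray) -> float:
    """Frequency-weighted mean haplo-insufficiency over segregating alleles."""
    rows, inv = np.unique(pop.hap_allele, return_inverse=True)
    cnt = np.bincount(inv)
    sig = np.zeros(len(rows))
    for a_i in range(len(rows)):
        sel = hm[inv == a_i]
        mh = sel[:, 4:7].mean(axis=0)   # c_hom moments, allele-averaged
        m1v = sel[:, 1:4].mean(axis=0)  # c = 1 moments
        qh = (2 * mh[1] - mh[2]) / mh[0] if mh[0] > 0 else 0.0
        q1 = (2 * m1v[1] - m1v[2]) / m1v[0] if m1v[0] > 0 else 0.0
        w_hom = -math.expm1(-cfg.d * qh)
        w_hemi = -math.expm1(-cfg.d * q1)
        sig[a_i] = (w_hom - w_hemi) / w_hemi if w_hemi > 0 else 0.0
    return float(np.average(sig, weights=cnt))


def _probe_s0(pop: Population, cfg: SimulationConfig, hm, w_geno,
              rng: np.random.Generator) -> float:
    """s0 = mean probe log fitness - population mean log fitness."""
    n_mei = cfg.n_mei

    def logfit(w):
        return np.log(np.maximum(1.0 - (1.0 - w) ** n_mei, 1e-300))

    m1h, m2h, m3h = hm[:, 1], hm[:, 2], hm[:, 3]
    dist = cfg.affinity_distribution()
    acc = 0.0
    for _ in range(cfg.s0_probes):
        y = dist.sample(cfg.h, rng)
        xp = y / (1.0 + y)
        p1, p2, p3 = xp.mean(), (xp ** 2).mean(), (xp ** 3).mean()
        qh = (2 * p2 - p3 + 2 * m2h - m3h) / (p1 + m1h)
        acc += logfit(-np.expm1(-cfg.d * qh)).mean()
    return acc / cfg.s0_probes - float(logfit(w_geno).mean())


def run(config: SimulationConfig,
        init_population: Population | None = None,
        checkpoint_dir: str | Path | None = None,
        checkpoint_interval: int | None = None) -> SimulationResult:
    """Run a full simulation and summarize the equilibrium regime.

    The master seed drives one NumPy generator for mutations, probe alleles
    and allele creation, and (once, at start) seeds the compiled meiosis
    kernel's own stream; draws are consumed in a fixed order, so trajectories
    are reproducible bit-for-bit at fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rng_state = _kernel_state_from(rng)
    if init_population is None:
        pop = Population.founder(cfg.N, cfg.h, cfg.affinity_distribution(),
                                 rng, L=cfg.L, prdm9_slot=cfg.prdm9_slot)
    else:
        pop = init_population
    eng = _Engine(pop, cfg, rng_state)

    G = cfg.generations
    rec = {k: np.full(G, np.nan) for k in
           ("D", "theta_bar", "n_alleles", "q_bar", "w_bar", "sigma_bar", "s0")}
    gen_idx = np.arange(1, G + 1)
    invasion_gens: list[int] = []
    crossed: set[int] = set()
    traj_rows: list[tuple] = []

    for g in range(G):
        eng.step(pop, rng)
        t = pop.generation
        cnt_rows = np.bincount(pop.hap_allele, minlength=pop.n_rows)
        live = np.flatnonzero(cnt_rows)
        f = cnt_rows[live] / (2.0 * pop.N)
        rec["D"][g] = 1.0 / np.sum(f ** 2)
        rec["n_alleles"][g] = len(live)
        if t % cfg.theta_interval == 0:
            th = _kernels.hap_theta(pop.hap_state, pop.hap_allele,
                                    pop.allele_cols, pop.h)
            rec["theta_bar"][g] = th.mean()
        for r, fr in zip(live, f):
            aid = int(pop.allele_ids[r])
            if aid not in crossed and fr > cfg.invasion_threshold:
                crossed.add(aid)
                invasion_gens.append(t)

        want_stats = (t % cfg.stats_interval == 0)
        want_s0 = (t % cfg.s0_interval == 0)
        if want_stats or want_s0:
            x = eng.x_arrays(pop)
            hm, q_geno, w_geno = _full_stats(pop, cfg, x)
            # per-haplotype value of its individual's genotype statistic
            q_hap = np.repeat(q_geno, 2)
            w_hap = np.repeat(w_geno, 2)
            rec["q_bar"][g] = q_hap.mean()
            rec["w_bar"][g] = w_hap.mean()
            rec["sigma_bar"][g] = _sigma_bar(pop, cfg, hm)
            if want_s0:
                rec["s0"][g] = _probe_s0(pop, cfg, hm, w_geno, rng)
            if cfg.record_trajectory and want_stats:
                rows_u, inv = np.unique(pop.hap_allele, return_inverse=True)
                cw = np.bincount(inv).astype(float)
                for a_i, r in enumerate(rows_u):
                    sel = inv == a_i
                    traj_rows.append((
                        t, int(pop.allele_ids[r]), cw[a_i] / (2 * pop.N),
                        float(hm[sel, 0].mean()), float(hm[sel, 7].mean()),
                        float(q_hap[sel].mean()), float(w_hap[sel].mean())))
        if checkpoint_dir is not None and checkpoint_interval and t % checkpoint_interval == 0:
            path = Path(checkpoint_dir) / f"checkpoint_{t}.json"
            try:
                path.write_text(pop.to_json())
            except OSError as exc:  # surface with generation index
                raise OSError(f"checkpoint failed at generation {t}: {exc}") from exc

    scalars = pd.DataFrame({"generation": gen_idx, **rec}) if G else pd.DataFrame(
        columns=["generation", *rec.keys()])
    trajectory = (pd.DataFrame(traj_rows, columns=[
        "generation", "allele_id", "f", "theta", "mean_affinity", "q", "w"])
        if cfg.record_trajectory else None)

    summary: dict = {}
    if G > 0:
        post = scalars[scalars["generation"] > cfg.burn_in]
        inv_post = [t for t in invasion_gens if t > cfg.burn_in]
        tau = float(np.mean(np.diff(inv_post))) if len(inv_post) >= 2 else float("nan")
        summary = {
            "D": float(post["D"].mean()),
            "theta_bar": float(post["theta_bar"].mean()),
            "erosion": float(1.0 - post["theta_bar"].mean()),
            "q_bar": float(post["q_bar"].mean()),
            "w_bar": float(post["w_bar"].mean()),
            "sigma_bar": float(post["sigma_bar"].mean()),
            "s0": float(post["s0"].mean()),
            "fourNs0": float(4 * cfg.N * cfg.rescale * post["s0"].mean()),
            "tau": tau,
            "n_invasions": len(inv_post),
            "generations_averaged": int(len(post)),
            "rescale": cfg.rescale,
        }
    return SimulationResult(config=cfg, scalars=scalars, trajectory=trajectory,
                            summary=summary, population=pop)
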