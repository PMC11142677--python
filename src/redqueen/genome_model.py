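"""Genome representation for the PRDM9 Red Queen simulator.

The model genome is a single chromosome encoded as an array of ``L`` slots.
Each PRDM9 allele owns ``h`` distinct slots (its target sites), each with a
rescaled binding affinity ``y = [P]_tot * K`` drawn from an exponential law.
A haplotype is a chromosome: one PRDM9 allele plus an active/inactive state
for every target site currently registered in the population (sites of every
live allele exist on every chromosome; only inactivating variants segregate).

The population state is kept in flat NumPy arrays so that the meiosis kernel
can run as compiled code:

* ``col_pos``/``col_aff`` describe the registered target-site columns (slot
  index and affinity); the first ``sorted_prefix`` columns are sorted by
  position, newly born alleles append to an unsorted tail until the next
  compaction resorts everything (sortedness makes the CO arm exchange two
  slice copies);
* ``hap_state`` is a ``(2N, n_cols)`` uint8 matrix, 1 = active site;
* ``hap_allele`` maps each haplotype to a row of ``allele_cols``, the
  (n_rows, h) table listing each live allele's column indices.

Target sites never revert: inactivation (by mutation or by gene conversion
against an inactive template) is permanent for a given site instance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "AffinityDistribution",
    "Allele",
    "Haplotype",
    "Individual",
    "Population",
    "create_allele",
    "mutate_prdm9",
    "mutate_targets",
    "allele_frequencies",
]


class AffinityDistribution:
    """Exponential law for rescaled binding affinities.

    By default each new allele receives the midpoint quantiles of the
    exponential law in random genome order (``stratified=True``), so that
    every allele carries exactly the same affinity spectrum and alleles
    differ only through the erosion of their target sets. This matches the
    modelling assumption that fresh alleles are exchangeable: with i.i.d.
    draws instead (``stratified=False``), the finite number of sites per
    allele gives each allele an intrinsic "quality" (its realized mean
    symmetric-binding rate varies by a few permil of fertility), and in
    polymorphic regimes selection on that quality outweighs the erosion
    differential that drives the Red Queen. Both schemes have the exact
    exponential marginal across sites.

    Parameters
    ----------
    mean_affinity : float
        Mean ``ȳ`` of the exponential law. Samples are strictly positive.
    stratified : bool
        Quantile-stratified assignment (default) or i.i.d. draws.
    """

    def __init__(self, mean_affinity: float, stratified: bool = True):
        if not mean_affinity > 0:
            raise ValueError("mean_affinity must be positive")
        self.mean_affinity = float(mean_affinity)
        self.stratified = bool(stratified)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.stratified:
            u = (np.arange(size) + 0.5) / size
            return rng.permutation(-self.mean_affinity * np.log1p(-u))
        y = rng.exponential(self.mean_affinity, size=size)
        # exponential() can return exactly 0.0; affinities are strictly positive
        while np.any(y == 0.0):
            y[y == 0.0] = rng.exponential(self.mean_affinity, size=int((y == 0.0).sum()))
        return y

    def __repr__(self) -> str:  # pragma: no cover
        return (f"AffinityDistribution(mean_affinity={self.mean_affinity}, "
                f"stratified={self.stratified})")


@dataclass
class Allele:
    """A PRDM9 variant: ``h`` target loci with their affinities.

    Immutable after creation except for ``row``, the bookkeeping index of
    its entry in the population's live-allele table (updated on compaction).
    """

    allele_id: int
    birth_generation: int
    loci: np.ndarray        # int64[h], distinct slot indices in [0, L)
    affinities: np.ndarray  # float64[h], strictly positive
    row: int = -1

    @property
    def h(self) -> int:
        return len(self.loci)


@dataclass
class Haplotype:
    """One chromosome: PRDM9 allele id + the set of inactivated target loci."""

    prdm9_allele: int
    inactive_loci: set = field(default_factory=set)


@dataclass
class Individual:
    """Two haplotypes; the genotype sets the per-allele dosage multiplier."""

    hap_a: Haplotype
    hap_b: Haplotype

    def dosage(self, c_hom: float) -> float:
        """Dosage multiplier ``c``: ``c_hom`` for a homozygote, 1 otherwise."""
        return float(c_hom) if self.hap_a.prdm9_allele == self.hap_b.prdm9_allele else 1.0


class SlotPoolExhausted(RuntimeError):
    """No room left on the chromosome for a new allele's target sites."""


class Population:
    """A population of N diploid individuals with flat array state."""

    def __init__(self, N: int, h: int, affinity_dist: AffinityDistribution,
                 L: int | None = None, prdm9_slot: int | None = None):
        if N < 2:
            raise ValueError("N must be >= 2")
        self.N = int(N)
        self.h = int(h)
        self.affinity_dist = affinity_dist
        self.L = int(L) if L is not None else max(1_000_000, 200 * self.h)
        self.prdm9_pos = int(prdm9_slot) if prdm9_slot is not None else self.L // 2
        self.generation = 0

        self.registry: dict[int, Allele] = {}
        self._next_allele_id = 0
        self._occupied = np.zeros(self.L, dtype=bool)
        self._occupied[self.prdm9_pos] = True

        self._cap = max(4 * self.h, 1024)
        self.n_cols = 0
        self.sorted_prefix = 0
        self._dead_cols = 0
        self.col_aff = np.zeros(self._cap)
        self.col_pos = np.zeros(self._cap, dtype=np.int64)
        self.hap_state = np.zeros((2 * self.N, self._cap), dtype=np.uint8)
        self.hap_allele = np.zeros(2 * self.N, dtype=np.int64)

        self._row_cap = 16
        self.n_rows = 0
        self.allele_ids = np.full(self._row_cap, -1, dtype=np.int64)
        self.allele_cols = np.zeros((self._row_cap, self.h), dtype=np.int64)
        self._n_occupied = 1  # the PRDM9 slot
        # bumped whenever the column layout changes (occupancy caches key on it)
        self.version = 0
        # bumped only when existing columns move (compaction); appends keep it
        self.layout_epoch = 0

    # ------------------------------------------------------------------ setup

    @classmethod
    def founder(cls, N: int, h: int, affinity_dist: AffinityDistribution,
                rng: np.random.Generator, L: int | None = None,
                prdm9_slot: int | None = None) -> "Population":
        """Population monomorphic for a single fresh allele, all sites active."""
        pop = cls(N, h, affinity_dist, L=L, prdm9_slot=prdm9_slot)
        a = create_allele(pop, affinity_dist, rng)
        pop.hap_allele[:] = a.row
        pop.compact()
        return pop

    # ------------------------------------------------------- column plumbing

    def _grow_cols(self, needed: int) -> None:
        cap = self._cap
        while cap < needed:
            cap *= 2
        for name, dtype in (("col_aff", float), ("col_pos", np.int64)):
            new = np.zeros(cap, dtype=dtype)
            new[: self.n_cols] = getattr(self, name)[: self.n_cols]
            setattr(self, name, new)
        new_state = np.zeros((2 * self.N, cap), dtype=np.uint8)
        new_state[:, : self.n_cols] = self.hap_state[:, : self.n_cols]
        self.hap_state = new_state
        self._cap = cap

    def _grow_rows(self) -> None:
        cap = 2 * self._row_cap
        ids = np.full(cap, -1, dtype=np.int64)
        cols = np.zeros((cap, self.h), dtype=np.int64)
        ids[: self.n_rows] = self.allele_ids[: self.n_rows]
        cols[: self.n_rows] = self.allele_cols[: self.n_rows]
        self.allele_ids, self.allele_cols, self._row_cap = ids, cols, cap

    def _draw_free_slots(self, k: int, rng: np.random.Generator) -> np.ndarray:
        n_free = self.L - self._n_occupied
        if n_free < k:
            raise SlotPoolExhausted(
                f"need {k} free slots, only {n_free} of L={self.L} left; increase L"
            )
        # rejection sampling = uniform over free slots; occupancy is kept low
        out = np.empty(k, dtype=np.int64)
        got = 0
        while got < k:
            cand = rng.integers(0, self.L, size=2 * (k - got))
            for c in cand:
                if not self._occupied[c]:
                    self._occupied[c] = True
                    out[got] = c
                    got += 1
                    if got == k:
                        break
        self._n_occupied += k
        return out

    def register_allele(self, allele: Allele) -> None:
        """Append the allele's columns (tail); all 2N haplotypes start active."""
        start = self.n_cols
        if start + allele.h > self._cap:
            self._grow_cols(start + allele.h)
        if self.n_rows == self._row_cap:
            self._grow_rows()
        sl = slice(start, start + allele.h)
        self.col_aff[sl] = allele.affinities
        self.col_pos[sl] = allele.loci
        self.hap_state[:, sl] = 1
        allele.row = self.n_rows
        self.allele_ids[self.n_rows] = allele.allele_id
        self.allele_cols[self.n_rows] = np.arange(start, start + allele.h)
        self.n_rows += 1
        self.n_cols += allele.h
        self.registry[allele.allele_id] = allele
        self.version += 1

    # --------------------------------------------------------------- queries

    def allele_counts(self) -> dict[int, int]:
        rows, counts = np.unique(self.hap_allele, return_counts=True)
        return {int(self.allele_ids[r]): int(c) for r, c in zip(rows, counts)}

    def hap_allele_ids(self) -> np.ndarray:
        return self.allele_ids[self.hap_allele]

    def block_state(self, idx: int, allele: Allele) -> np.ndarray:
        """Active/inactive state of one allele's sites on one haplotype."""
        return self.hap_state[idx, self.allele_cols[allele.row]]

    def haplotype_view(self, idx: int) -> Haplotype:
        inactive: set[int] = set()
        for a in self.registry.values():
            st = self.block_state(idx, a)
            inactive.update(int(p) for p in a.loci[st == 0])
        return Haplotype(prdm9_allele=int(self.allele_ids[self.hap_allele[idx]]),
                         inactive_loci=inactive)

    def individual_view(self, i: int) -> Individual:
        return Individual(self.haplotype_view(2 * i), self.haplotype_view(2 * i + 1))

    def theta_per_haplotype(self) -> np.ndarray:
        """Fraction of active own-allele sites, per haplotype."""
        return _kernels.hap_theta(self.hap_state, self.hap_allele,
                                  self.allele_cols, self.h)

    # --------------------------------------------------- garbage collection

    def drop_dead_alleles(self) -> None:
        """Unregister alleles with frequency 0 and free their genome slots.

        Their columns remain until :meth:`compact` rewrites the state matrix.
        """
        live_rows = set(int(r) for r in np.unique(self.hap_allele))
        dead = [i for i, a in self.registry.items() if a.row not in live_rows]
        for i in dead:
            a = self.registry.pop(i)
            self._occupied[a.loci] = False
            self._n_occupied -= a.h
            self._dead_cols += a.h

    def compact(self) -> None:
        """Drop dead alleles' columns and resort everything by position."""
        alleles = sorted(self.registry.values(), key=lambda a: a.allele_id)
        old_cols = np.concatenate([self.allele_cols[a.row] for a in alleles]) \
            if alleles else np.zeros(0, dtype=np.int64)
        order = np.argsort(self.col_pos[old_cols], kind="stable")
        src = old_cols[order]
        n_new = len(src)
        inv = np.full(self.n_cols, -1, dtype=np.int64)
        inv[src] = np.arange(n_new)

        new_aff = np.zeros(self._cap)
        new_pos = np.zeros(self._cap, dtype=np.int64)
        new_aff[:n_new] = self.col_aff[src]
        new_pos[:n_new] = self.col_pos[src]
        new_state = np.zeros((2 * self.N, self._cap), dtype=np.uint8)
        _kernels.gather_cols(self.hap_state, src, new_state)
        self.col_aff, self.col_pos, self.hap_state = new_aff, new_pos, new_state

        row_map = np.full(self.n_rows, -1, dtype=np.int64)
        new_ids = np.full(self._row_cap, -1, dtype=np.int64)
        new_cols = np.zeros((self._row_cap, self.h), dtype=np.int64)
        for new_row, a in enumerate(alleles):
            row_map[a.row] = new_row
            new_ids[new_row] = a.allele_id
            new_cols[new_row] = inv[self.allele_cols[a.row]]
            a.row = new_row
        self.allele_ids, self.allele_cols = new_ids, new_cols
        self.n_rows = len(alleles)
        self.hap_allele = row_map[self.hap_allele]
        self.n_cols = n_new
        self.sorted_prefix = n_new
        self._dead_cols = 0
        self.version += 1
        self.layout_epoch += 1

    def gc(self, force: bool = False) -> None:
        self.drop_dead_alleles()
        tail = self.n_cols - self.sorted_prefix
        if force or (self._dead_cols + tail) > 0.25 * max(self.n_cols, 1):
            self.compact()

    # ---------------------------------------------------------- serialization

    def to_json(self) -> str:
        """Serialize to the checkpoint JSON schema (documented in README)."""
        alleles = [
            {
                "allele_id": a.allele_id,
                "birth_generation": a.birth_generation,
                "loci": a.loci.tolist(),
                "affinities": a.affinities.tolist(),
            }
            for a in sorted(self.registry.values(), key=lambda a: a.allele_id)
        ]
        haps = []
        for idx in range(2 * self.N):
            inact: dict[str, list[int]] = {}
            for a in self.registry.values():
                zero = np.flatnonzero(self.block_state(idx, a) == 0)
                if len(zero):
                    inact[str(a.allele_id)] = zero.tolist()
            haps.append({"prdm9_allele": int(self.allele_ids[self.hap_allele[idx]]),
                         "inactive_site_index": inact})
        return json.dumps({
            "schema": "redqueen-population-v1",
            "N": self.N, "h": self.h, "L": self.L,
            "prdm9_slot": self.prdm9_pos,
            "mean_affinity": self.affinity_dist.mean_affinity,
            "stratified_affinities": self.affinity_dist.stratified,
            "generation": self.generation,
            "next_allele_id": self._next_allele_id,
            "alleles": alleles,
            "haplotypes": haps,
        })

    @classmethod
    def from_json(cls, text: str) -> "Population":
        d = json.loads(text)
        if d.get("schema") != "redqueen-population-v1":
            raise ValueError("unrecognized population schema")
        dist = AffinityDistribution(d["mean_affinity"],
                                    stratified=d.get("stratified_affinities", True))
        pop = cls(d["N"], d["h"], dist, L=d["L"], prdm9_slot=d["prdm9_slot"])
        pop.generation = d["generation"]
        pop._next_allele_id = d["next_allele_id"]
        for ad in d["alleles"]:
            a = Allele(ad["allele_id"], ad["birth_generation"],
                       np.asarray(ad["loci"], dtype=np.int64),
                       np.asarray(ad["affinities"]))
            pop._occupied[a.loci] = True
            pop._n_occupied += len(a.loci)
            pop.register_allele(a)
        for idx, hd in enumerate(d["haplotypes"]):
            a = pop.registry[hd["prdm9_allele"]]
            pop.hap_allele[idx] = a.row
            for aid, zeros in hd["inactive_site_index"].items():
                b = pop.registry[int(aid)]
                cols = pop.allele_cols[b.row][np.asarray(zeros, dtype=np.int64)]
                pop.hap_state[idx, cols] = 0
        pop.compact()
        return pop


# --------------------------------------------------------------- operations


def create_allele(population: Population, affinity_dist: AffinityDistribution,
                  rng: np.random.Generator) -> Allele:
    """Create and register a fresh PRDM9 allele.

    ``h`` distinct loci are drawn uniformly among the free genome slots and
    ``h`` affinities i.i.d. from ``affinity_dist``. All 2N haplotypes are
    active at the new loci (sites are monomorphic for the active variant at
    the birth of the allele).
    """
    h = population.h
    loci = population._draw_free_slots(h, rng)
    aff = affinity_dist.sample(h, rng)
    a = Allele(population._next_allele_id, population.generation, loci, aff)
    population._next_allele_id += 1
    population.register_allele(a)
    return a


def mutate_prdm9(population: Population, u: float,
                 rng: np.random.Generator) -> Population:
    """Each of the 2N gene copies is replaced w.p. ``u`` by a fresh allele."""
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must be in [0, 1]")
    if u == 0.0:
        return population
    hit = np.flatnonzero(rng.random(2 * population.N) < u)
    for idx in hit:
        a = create_allele(population, population.affinity_dist, rng)
        population.hap_allele[idx] = a.row
    return population


def mutate_targets(population: Population, v: float,
                   rng: np.random.Generator) -> Population:
    """Inactivate each active site instance independently w.p. ``v``.

    Applied per haploid copy per generation; inactive sites never revert.
    For small ``v`` the per-instance Bernoulli field is drawn by the standard
    count-then-place method (hit probability ``1 - e^-v`` per instance, i.e.
    ``v`` to first order, which is the regime the model operates in).
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError("v must be in [0, 1]")
    if v == 0.0 or population.n_cols == 0:
        return population
    M = 2 * population.N * population.n_cols
    if v > 0.05:
        mask = rng.random((2 * population.N, population.n_cols)) < v
        population.hap_state[:, : population.n_cols][mask] = 0
        return population
    k = rng.binomial(M, v)
    if k:
        flat = rng.integers(0, M, size=k)
        rows, cols = np.divmod(flat, population.n_cols)
        population.hap_state[rows, cols] = 0
    return population


def allele_frequencies(population: Population) -> dict[int, float]:
    """Allele frequencies over the 2N haplotypes; values sum to 1."""
    if population.N == 0:
        raise ValueError("empty population")
    return {i: c / (2 * population.N) for i, c in population.allele_counts().items()}
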