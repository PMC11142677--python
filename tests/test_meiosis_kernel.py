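import numpy as np
import pytest

from redqueen.genome_model import (AffinityDistribution, Allele, Haplotype,
                                   Individual, Population)
from redqueen.meiosis_kernel import (CONTROL_NO_SYMMETRY, SYMMETRY_REQUIRED,
                                     ChromatidState, bind_chromatids,
                                     find_symmetric_dsbs, occupancy,
                                     place_dsbs, resolve_meiosis)
from redqueen import summary_stats as ss


def fresh_individual(rng, h=60, ybar=1.0, hom=True, n_alleles=None):
    pop = Population.founder(2, h, AffinityDistribution(ybar), rng, L=50_000)
    from redqueen.genome_model import create_allele
    if not hom:
        create_allele(pop, pop.affinity_dist, rng)
    alleles = sorted(pop.registry.values(), key=lambda a: a.allele_id)
    ids = [a.allele_id for a in alleles]
    hap_a = Haplotype(prdm9_allele=ids[0])
    hap_b = Haplotype(prdm9_allele=ids[0] if hom else ids[1])
    return Individual(hap_a, hap_b), {a.allele_id: a for a in alleles}


class TestOccupancy:
    @pytest.mark.parametrize("y, c, expected", [
        (1.0, 1.0, 0.5),
        (0.0, 2.0, 0.0),
        (6.0, 2.0, 12.0 / 13.0),
    ])
    def test_values(self, y, c, expected):
        assert occupancy(y, c) == pytest.approx(expected)

    def test_monotone_in_y_and_c(self):
        y = np.linspace(0.0, 5.0, 50)
        x = occupancy(y, 1.0)
        assert np.all(np.diff(x) > 0)
        assert np.all(occupancy(y[1:], 2.0) > occupancy(y[1:], 1.0))

    def test_rejects_negative_affinity_and_dosage(self):
        with pytest.raises(ValueError):
            occupancy(-0.1)
        with pytest.raises(ValueError):
            occupancy(1.0, c=0.0)


class TestBindChromatids:
    def test_inactive_sites_never_bound(self, rng):
        ind, reg = fresh_individual(rng)
        a = next(iter(reg.values()))
        all_loci = set(a.loci.tolist())
        ind.hap_a.inactive_loci = set(all_loci)
        ind.hap_b.inactive_loci = set(all_loci)
        for ch in bind_chromatids(ind, reg, 1.0, rng):
            assert not ch.bound_loci

    def test_saturating_affinity_binds_everywhere(self, rng):
        ind, reg = fresh_individual(rng, ybar=1.0)
        a = next(iter(reg.values()))
        a.affinities[:] = 1e9
        for ch in bind_chromatids(ind, reg, 1.0, rng):
            assert ch.bound_loci == set(a.loci.tolist())

    def test_mean_bound_count_matches_binomial(self, rng):
        # homozygote with dosage: E[k] = 4 h occupancy(y, c_hom)
        h, y, c = 40, 0.8, 2.0
        ind, reg = fresh_individual(rng, h=h, ybar=1.0)
        a = next(iter(reg.values()))
        a.affinities[:] = y
        reps = 2000
        k = sum(sum(len(c_.bound_loci) for c_ in bind_chromatids(ind, reg, c, rng))
                for _ in range(reps)) / reps
        x = occupancy(y, c)
        expect = 4 * h * x
        se = np.sqrt(4 * h * x * (1 - x) / reps)
        assert abs(k - expect) < 4 * se


class TestPlaceDsbs:
    def _chromatids(self, bound_sets):
        out = []
        for t, b in enumerate(bound_sets):
            out.append(ChromatidState(parent="A" if t < 2 else "B",
                                      sister_index=t % 2, prdm9_allele=0,
                                      bound_loci=set(b)))
        return out

    def test_no_binding_fails(self, rng):
        _, reason = place_dsbs(self._chromatids([[], [], [], []]), 6.0, rng)
        assert reason == "no_binding"

    def test_all_break_when_k_below_d(self, rng):
        chroms, reason = place_dsbs(self._chromatids([[1], [2], [3], []]), 6.0, rng)
        assert reason is None
        assert [c.dsb_loci for c in chroms] == [{1}, {2}, {3}, set()]

    def test_mean_dsb_count_is_d(self, rng):
        loci = list(range(250))
        total = 0
        reps = 400
        for _ in range(reps):
            chroms, _ = place_dsbs(self._chromatids([loci] * 4), 6.0, rng)
            total += sum(len(c.dsb_loci) for c in chroms)
        assert abs(total / reps - 6.0) < 4 * np.sqrt(6.0 / reps)


class TestFindSymmetricDsbs:
    def _base(self):
        return [ChromatidState("A", 0, 0), ChromatidState("A", 1, 0),
                ChromatidState("B", 0, 0), ChromatidState("B", 1, 0)]

    def test_dsb_bound_on_other_homolog_is_symmetric(self):
        ch = self._base()
        ch[0].bound_loci = {7}
        ch[0].dsb_loci = {7}
        ch[2].bound_loci = {7}
        assert find_symmetric_dsbs(ch) == {(0, 7)}

    def test_sister_binding_does_not_count(self):
        ch = self._base()
        ch[0].bound_loci = {7}
        ch[0].dsb_loci = {7}
        ch[1].bound_loci = {7}  # sister chromatid, same parent
        assert find_symmetric_dsbs(ch) == set()

    def test_no_dsbs_empty(self):
        ch = self._base()
        ch[0].bound_loci = {1, 2}
        ch[2].bound_loci = {1, 2}
        assert find_symmetric_dsbs(ch) == set()


class TestResolveMeiosis:
    def test_saturating_homozygote_always_succeeds(self, rng):
        ind, reg = fresh_individual(rng)
        next(iter(reg.values())).affinities[:] = 1e9
        for _ in range(20):
            out = resolve_meiosis(ind, reg, SYMMETRY_REQUIRED, 6.0, 1.0, rng)
            assert out.success
            assert out.co_locus is not None

    def test_fully_inactive_genotype_fails_no_binding(self, rng):
        ind, reg = fresh_individual(rng)
        a = next(iter(reg.values()))
        ind.hap_a.inactive_loci = set(a.loci.tolist())
        ind.hap_b.inactive_loci = set(a.loci.tolist())
        out = resolve_meiosis(ind, reg, SYMMETRY_REQUIRED, 6.0, 1.0, rng)
        assert not out.success and out.failure_reason == "no_binding"
        assert out.gamete is None

    def test_conversion_copies_inactive_template(self, rng):
        # hap_b carries the inactivating variant at one locus; any DSB there
        # sits on a hap_a chromatid and must repair to the inactive state.
        ind, reg = fresh_individual(rng, h=40, ybar=5.0)
        a = next(iter(reg.values()))
        lstar = int(a.loci[3])
        ind.hap_b.inactive_loci = {lstar}
        seen = 0
        for _ in range(400):
            out = resolve_meiosis(ind, reg, SYMMETRY_REQUIRED, 8.0, 1.0, rng,
                                  trace=True)
            if not out.success:
                continue
            gchrom = out.trace["gamete_chromatid"]
            for rec in out.trace["dsbs"]:
                if rec["locus"] == lstar and rec["chromatid"] == gchrom:
                    seen += 1
                    assert lstar in out.gamete.inactive_loci
            # conversion never activates: DSBs at loci where the template is
            # inactive always leave the gamete inactive there (checked above);
            # a site inactive on both haplotypes can never become active
            if lstar in ind.hap_a.inactive_loci:
                assert lstar in out.gamete.inactive_loci
        assert seen > 0  # the assertion above actually fired

    def test_exactly_one_co_per_success(self, rng):
        ind, reg = fresh_individual(rng, h=50, ybar=2.0)
        for _ in range(50):
            out = resolve_meiosis(ind, reg, SYMMETRY_REQUIRED, 6.0, 1.0, rng,
                                  trace=True)
            if out.success:
                assert out.co_locus is not None
                assert len(out.trace["co_chromatids"]) == 2
                t_broken, t_partner = out.trace["co_chromatids"]
                assert (t_broken < 2) != (t_partner < 2)  # opposite homologs

    def test_control_mode_needs_only_one_dsb(self, rng):
        # one active locus on hap_a only: never symmetric, but control passes
        ind, reg = fresh_individual(rng, h=30, ybar=5.0)
        a = next(iter(reg.values()))
        keep = int(a.loci[0])
        ind.hap_a.inactive_loci = set(a.loci.tolist()) - {keep}
        ind.hap_b.inactive_loci = set(a.loci.tolist())
        n_ok_sym = n_ok_ctrl = 0
        for _ in range(120):
            n_ok_sym += resolve_meiosis(ind, reg, SYMMETRY_REQUIRED, 6.0, 1.0, rng).success
            n_ok_ctrl += resolve_meiosis(ind, reg, CONTROL_NO_SYMMETRY, 6.0, 1.0, rng).success
        assert n_ok_sym == 0
        assert n_ok_ctrl > 60

    def test_success_rate_matches_closed_form(self, rng):
        # load-bearing link between the kernel and the analytic layer
        ind, reg = fresh_individual(rng, h=400, ybar=0.2)
        a = next(iter(reg.values()))
        w_pred = ss.fertility(ss.q_hom(ss.moments(a.affinities, 2.0)), 8.0)
        n = 3000
        emp = sum(resolve_meiosis(ind, reg, SYMMETRY_REQUIRED, 8.0, 2.0, rng).success
                  for _ in range(n)) / n
        se = np.sqrt(w_pred * (1 - w_pred) / n)
        assert abs(emp - w_pred) < 3 * se

    def test_success_monotone_in_dosage(self, rng):
        ind, reg = fresh_individual(rng, h=300, ybar=0.2)
        a = next(iter(reg.values()))
        rates = [ss.fertility(ss.q_hom(ss.moments(a.affinities, c)), 8.0)
                 for c in (1.0, 1.5, 2.0)]
        assert rates[0] < rates[1] < rates[2]

    def test_reference_steps_consistent_with_fused_kernel(self, rng):
        # symmetric fraction among DSBs from the reference steps matches the
        # analytic q that the fused kernel was validated against
        ind, reg = fresh_individual(rng, h=200, ybar=0.5)
        a = next(iter(reg.values()))
        q_pred = ss.q_hom(ss.moments(a.affinities, 1.0))
        tot = sym = 0
        for _ in range(300):
            ch = bind_chromatids(ind, reg, 1.0, rng)
            ch, reason = place_dsbs(ch, 6.0, rng)
            if reason:
                continue
            n_dsb = sum(len(c.dsb_loci) for c in ch)
            tot += n_dsb
            sym += len(find_symmetric_dsbs(ch))
        se = np.sqrt(q_pred * (1 - q_pred) / tot)
        assert abs(sym / tot - q_pred) < 4 * se
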