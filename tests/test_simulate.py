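"""Synthetic genome/read generator: determinism, conservation laws, recovery."""

import numpy as np
import pytest

from mitorecomb import (PackingError, RepeatSpec, apply_recombination,
                        evaluate_recovery, generate_genome, simulate_reads)
from mitorecomb.alignment import pair_identity
from mitorecomb.mtio import revcomp
from mitorecomb.recombination import (build_conformation_set,
                                      count_read_support, screen_recombinants)
from mitorecomb.repeats import find_repeat_pairs
from mitorecomb.simulate import SyntheticTruth, simulate_pair_reads


def test_identical_seeds_are_byte_identical():
    spec = [RepeatSpec(200, 99.0, "inverted")]
    g1, t1 = generate_genome(20_000, spec, seed=77)
    g2, t2 = generate_genome(20_000, spec, seed=77)
    assert g1.seq == g2.seq and t1.repeats == t2.repeats
    r1, _ = simulate_reads([g1], [1.0], 50, mean_len=5000, error_rate=0.05, seed=9)
    r2, _ = simulate_reads([g2], [1.0], 50, mean_len=5000, error_rate=0.05, seed=9)
    assert r1 == r2


def test_planted_exact_repeat_recovered_by_scan():
    genome, truth = generate_genome(50_000, [RepeatSpec(2000, 100.0, "direct")],
                                    seed=31)
    pairs = find_repeat_pairs(genome)
    assert len(pairs) == 1
    (found,) = pairs
    (ps, pe), (qs, qe) = truth.repeats[0].copy1, truth.repeats[0].copy2
    assert found.copy1[0] <= ps and pe <= found.copy1[1]
    assert found.copy2[0] <= qs and qe <= found.copy2[1]
    assert found.length - 2000 < 10  # at most a few chance boundary matches
    assert found.identity == 100.0


def test_zero_specs_yield_no_repeats():
    genome, truth = generate_genome(20_000, [], seed=32)
    assert truth.repeats == []
    assert find_repeat_pairs(genome) == []


def test_degraded_identity_is_close_to_target():
    genome, truth = generate_genome(20_000, [RepeatSpec(1000, 99.0, "direct")],
                                    seed=33)
    pair = truth.repeats[0]
    s1 = genome.seq[pair.copy1[0] - 1:pair.copy1[1]]
    s2 = genome.seq[pair.copy2[0] - 1:pair.copy2[1]]
    assert abs(pair_identity(s1, s2) - 99.0) <= 0.2


def test_infeasible_packing_raises():
    with pytest.raises(PackingError):
        generate_genome(5000, [RepeatSpec(2000, 100.0, "direct")], seed=34)


# ---------------------------------------------------------------------------
# recombination products


def test_inversion_conserves_length_composition_and_is_involution():
    genome, truth = generate_genome(20_000, [RepeatSpec(300, 100.0, "inverted")],
                                    seed=35)
    pair = truth.repeats[0]
    (product,) = apply_recombination(genome, pair)
    assert product.length == genome.length
    # double-stranded composition: A+T and G+C totals are strand-independent
    def at_gc(s):
        return s.count("A") + s.count("T"), s.count("G") + s.count("C")
    assert at_gc(product.seq) == at_gc(genome.seq)
    (restored,) = apply_recombination(product, pair)
    assert restored.seq == genome.seq


def test_direct_repeat_on_circle_splits_into_two_subcircles():
    genome, truth = generate_genome(30_000, [RepeatSpec(400, 100.0, "direct")],
                                    seed=36, topology="circular")
    pair = truth.repeats[0]
    products = apply_recombination(genome, pair)
    assert len(products) == 2
    assert all(p.topology == "circular" for p in products)
    assert sum(p.length for p in products) == genome.length


def test_direct_repeat_on_linear_molecule_excises_a_circle():
    genome, truth = generate_genome(30_000, [RepeatSpec(400, 100.0, "direct")],
                                    seed=37, topology="linear")
    pair = truth.repeats[0]
    deletion, circle = apply_recombination(genome, pair)
    assert deletion.topology == "linear" and circle.topology == "circular"
    assert deletion.length + circle.length == genome.length


def test_overlapping_copies_are_rejected():
    from mitorecomb.repeats import RepeatPair
    genome, _ = generate_genome(20_000, [], seed=38)
    nested = RepeatPair(1, (100, 400), (300, 600), "direct", 100.0, 300, "medium")
    with pytest.raises(ValueError):
        apply_recombination(genome, nested)


# ---------------------------------------------------------------------------
# read simulation


def test_error_free_reads_are_substrings():
    genome, _ = generate_genome(30_000, [], seed=39, topology="circular")
    reads, records = simulate_reads([genome], [1.0], 60, mean_len=5000, seed=40)
    doubled = genome.seq + genome.seq
    for (_, seq), rec in zip(reads, records):
        assert rec.n_errors == 0
        assert (seq in doubled) or (revcomp(seq) in doubled)


def test_mixture_weights_follow_binomial():
    a, _ = generate_genome(30_000, [], seed=41)
    b, _ = generate_genome(30_000, [], seed=42)
    _, records = simulate_reads([a, b], [0.5, 0.5], 400, mean_len=5000, seed=43)
    n_a = sum(r.source == a.id for r in records)
    se = (400 * 0.25) ** 0.5
    assert abs(n_a - 200) <= 3 * se


def test_read_length_mean_matches_request():
    genome, _ = generate_genome(200_000, [], seed=44)
    _, records = simulate_reads([genome], [1.0], 10_000, mean_len=15_000, seed=45)
    mean = np.mean([r.length for r in records])
    assert abs(mean - 15_000) / 15_000 < 0.02


def test_weights_must_sum_to_one():
    genome, _ = generate_genome(20_000, [], seed=46)
    with pytest.raises(ValueError):
        simulate_reads([genome, genome], [0.9, 0.2], 10, mean_len=2000, seed=1)


# ---------------------------------------------------------------------------
# recovery evaluation


def _recover(genome, pair, fraction, n_reads, seed, config):
    confs = screen_recombinants(build_conformation_set(pair, genome, config),
                                genome, config)
    reads, _ = simulate_pair_reads(genome, pair, fraction, n_reads,
                                   mean_len=3000, seed=seed, config=config)
    return count_read_support(confs, reads, config)


def test_recovery_of_planted_quarter_fraction(config):
    genome, truth = generate_genome(20_000, [RepeatSpec(300, 100.0, "direct")],
                                    seed=47, topology="circular")
    pair = truth.repeats[0]
    truth.alt_fractions = {pair.id: 0.25}
    res = _recover(genome, pair, 0.25, 400, 48, config)
    report = evaluate_recovery([res], truth)
    assert report.loc[0, "abs_error"] < 0.07  # 3 binomial SE at n=400
    assert report.loc[0, "called_active"]


def test_all_master_mixture_has_no_false_actives(config):
    genome, truth = generate_genome(20_000, [RepeatSpec(300, 100.0, "direct")],
                                    seed=49, topology="circular")
    pair = truth.repeats[0]
    res = _recover(genome, pair, 0.0, 200, 50, config)
    report = evaluate_recovery([res], truth)
    assert report.loc[0, "estimated_fraction"] == 0.0
    assert not report.loc[0, "called_active"]


def test_recovery_rejects_unknown_pair_id(config):
    from mitorecomb.recombination import ReadSupportResult
    truth = SyntheticTruth(seed=0, genome_id="g")
    with pytest.raises(ValueError):
        evaluate_recovery([ReadSupportResult(99, 1, 1)], truth)
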