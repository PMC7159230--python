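"""Conformation references, genome screening, and read-support counting."""

import pytest

from mitorecomb import (GenomeSequence, PipelineConfig, ReadSupportResult,
                        build_conformation_set, count_read_support,
                        read_supports_reference, screen_recombinants)
from mitorecomb.mtio import revcomp
from mitorecomb.simulate import (RepeatSpec, generate_genome, _mutate,
                                 recombination_products, simulate_pair_reads)

import numpy as np


@pytest.fixture(scope="module")
def direct_exact():
    """10-kb toy genome with one planted 300-bp exact direct repeat."""
    genome, truth = generate_genome(10_000, [RepeatSpec(300, 100.0, "direct")],
                                    seed=11, margin=1100, topology="circular")
    return genome, truth.repeats[0]


@pytest.fixture(scope="module")
def inverted_exact():
    genome, truth = generate_genome(12_000, [RepeatSpec(300, 100.0, "inverted")],
                                    seed=12, margin=1100, topology="circular")
    return genome, truth.repeats[0]


# ---------------------------------------------------------------------------
# percentage arithmetic


@pytest.mark.parametrize("alt,master,alt_pct,master_pct", [
    (8, 9, 47.06, 52.94),
    (27, 28, 49.09, 50.91),
    (86, 81, 51.50, 48.50),
    (19, 219, 7.98, 92.02),
])
def test_support_percentages_round_half_up(alt, master, alt_pct, master_pct):
    res = ReadSupportResult(pair_id=1, reads_master=master, reads_alternative=alt)
    assert res.alt_percent == alt_pct
    assert res.master_percent == master_pct
    assert res.active


def test_percentages_undefined_without_reads():
    res = ReadSupportResult(pair_id=1, reads_master=0, reads_alternative=0)
    assert res.alt_percent is None and res.master_percent is None
    assert not res.active


# ---------------------------------------------------------------------------
# conformation construction


def test_exact_pair_yields_four_references(direct_exact, config):
    genome, pair = direct_exact
    confs = build_conformation_set(pair, genome, config)
    assert len(confs.references) == 4
    assert confs.n_master == 2 and confs.n_alternative == 2


def test_inexact_pair_yields_eight_references(config):
    genome, truth = generate_genome(10_000, [RepeatSpec(300, 99.33, "direct")],
                                    seed=13, margin=1100)
    confs = build_conformation_set(truth.repeats[0], genome, config)
    assert len(confs.references) == 8
    assert confs.n_master == 2 and confs.n_alternative == 6


def test_direct_alternatives_match_string_oracle(direct_exact, config):
    """Alternatives must equal the A+R+D and C+R+B concatenations built by hand."""
    genome, pair = direct_exact
    g = genome.seq
    fl = config.flank_len
    (s1, e1), (s2, e2) = pair.copy1, pair.copy2
    a = g[s1 - 1 - fl:s1 - 1]
    b = g[e1:e1 + fl]
    c = g[s2 - 1 - fl:s2 - 1]
    d = g[e2:e2 + fl]
    r = g[s1 - 1:e1]
    confs = build_conformation_set(pair, genome, config)
    masters = {x.seq for x in confs.references if x.role == "master"}
    alts = {x.seq for x in confs.references if x.role == "alternative"}
    assert masters == {a + r + b, c + r + d}
    assert alts == {a + r + d, c + r + b}


def test_masters_are_genome_substrings(direct_exact, inverted_exact, config):
    for genome, pair in (direct_exact, inverted_exact):
        confs = build_conformation_set(pair, genome, config)
        doubled = genome.seq + genome.seq  # circular wrap
        for ref in confs.references:
            if ref.role == "master":
                assert ref.seq in doubled


def test_inverted_alternatives_match_recombination_product(inverted_exact, config):
    """Each alternative junction must occur in the inversion product molecule."""
    genome, pair = inverted_exact
    confs = build_conformation_set(pair, genome, config)
    (product, _spans), = recombination_products(genome, pair)
    doubled = product.seq + product.seq
    both = doubled + "#" + revcomp(doubled)
    for ref in confs.references:
        if ref.role == "alternative":
            s, e = ref.repeat_span
            window = ref.seq[s - 1 - 200:e + 200]
            assert window in both
            assert window not in genome.seq + genome.seq + "#" + \
                revcomp(genome.seq + genome.seq)


# ---------------------------------------------------------------------------
# screening


def test_alternative_present_in_genome_is_removed(direct_exact, config):
    genome, pair = direct_exact
    confs = build_conformation_set(pair, genome, config)
    alt = next(r for r in confs.references if r.role == "alternative")
    # plant the recombinant sequence elsewhere in the molecule
    spiked = GenomeSequence("spiked", genome.seq + alt.seq, "linear")
    screened = screen_recombinants(confs, spiked, config)
    labels = {r.label for r in screened.references if r.role == "alternative"}
    assert alt.label not in labels
    assert len(labels) == 1  # the other junction shares only flanks: retained
    assert screened.n_master == 2  # masters never removed


def test_flank_sharing_alternatives_are_retained(direct_exact, config):
    genome, pair = direct_exact
    confs = screen_recombinants(build_conformation_set(pair, genome, config),
                                genome, config)
    assert confs.n_alternative == 2


def test_high_identity_shuffles_are_screened_out(config):
    """For identity<100, the A-R2-B style shuffles match the genome and go."""
    genome, truth = generate_genome(20_000, [RepeatSpec(2000, 99.5, "inverted")],
                                    seed=14, margin=1100)
    confs = build_conformation_set(truth.repeats[0], genome, config)
    screened = screen_recombinants(confs, genome, config)
    assert len(confs.references) == 8
    assert len(screened.references) == 6  # two shuffles located in the genome
    kept = {r.label for r in screened.references if r.role == "alternative"}
    assert kept == {"A-R1-rc(C)", "A-rc(R2)-rc(C)", "rc(D)-R1-B", "rc(D)-rc(R2)-B"}


# ---------------------------------------------------------------------------
# read support


def test_error_free_spanning_read_supports_master(direct_exact, config):
    genome, pair = direct_exact
    confs = build_conformation_set(pair, genome, config)
    master = confs.references[0]
    (s1, e1) = pair.copy1
    read = genome.seq[s1 - 1 - 500:e1 + 500]
    assert read_supports_reference(read, master, config)
    assert read_supports_reference(revcomp(read), master, config)


def test_short_flank_coverage_fails(direct_exact, config):
    genome, pair = direct_exact
    confs = build_conformation_set(pair, genome, config)
    master = confs.references[0]
    (s1, e1) = pair.copy1
    read = genome.seq[s1 - 1 - 150:e1 + 500]  # only 150 bp of left flank
    assert not read_supports_reference(read, master, config)


def test_noisy_read_below_identity_threshold_fails(direct_exact, config):
    genome, pair = direct_exact
    (s1, e1) = pair.copy1
    clean = genome.seq[s1 - 1 - 500:e1 + 500]
    noisy, n_err = _mutate(clean, 0.08, np.random.default_rng(3))
    assert n_err > 0.05 * len(clean)
    confs = build_conformation_set(pair, genome, config)
    assert not read_supports_reference(noisy, confs.references[0], config)


def test_master_only_reads_count_master_only(direct_exact, config):
    genome, pair = direct_exact
    confs = screen_recombinants(build_conformation_set(pair, genome, config),
                                genome, config)
    reads, _ = simulate_pair_reads(genome, pair, alt_fraction=0.0, n_reads=10,
                                   mean_len=3000, seed=21, config=config)
    res = count_read_support(confs, reads, config)
    assert (res.reads_master, res.reads_alternative) == (10, 0)
    assert not res.active


def test_mixture_counts_follow_binomial(direct_exact, config):
    genome, pair = direct_exact
    confs = screen_recombinants(build_conformation_set(pair, genome, config),
                                genome, config)
    n = 200
    reads, records = simulate_pair_reads(genome, pair, alt_fraction=0.5,
                                         n_reads=n, mean_len=3000, seed=22,
                                         config=config)
    res = count_read_support(confs, reads, config)
    assert res.reads_master + res.reads_alternative == n  # every read assigned once
    truth_alt = sum(r.role == "alternative" for r in records)
    assert res.reads_alternative == truth_alt
    se = (0.25 / n) ** 0.5
    assert abs(res.reads_alternative / n - 0.5) <= 3 * se


def test_empty_read_database(direct_exact, config):
    genome, pair = direct_exact
    confs = build_conformation_set(pair, genome, config)
    res = count_read_support(confs, [], config)
    assert (res.reads_master, res.reads_alternative) == (0, 0)
    assert res.alt_percent is None
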