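"""Protocol simulator: sonication, tagmentation, digestion, barcodes, PCR."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

import exoprof as xp
from exoprof.simulate import (
    Fragment,
    _Geometry,
    _merged_overlap_intervals,
    apply_barcode_scheme,
    lognormal_params,
    pcr_duplicate,
    simulate_fragments,
    tagment,
)


def _cfg(version, **kw):
    return xp.SimConfig.for_version(version, **kw)


# ---------------------------------------------------------------------------
# configuration


def test_config_validation_names_offending_field():
    with pytest.raises(xp.ConfigError, match="p_shoulder"):
        _cfg("exo5.0", p_shoulder=2.0)
    with pytest.raises(xp.ConfigError, match="dup_mean"):
        _cfg("seq", dup_mean=0.5)
    with pytest.raises(xp.ConfigError, match="version"):
        _cfg("exo9.9")
    with pytest.raises(xp.ConfigError, match="tn5_pwm"):
        _cfg("mentation", tn5_pwm=np.full((10, 4), 0.25))


def test_config_yaml_roundtrip(tmp_path):
    cfg = _cfg("nexus", seed=3, n_fragments=123)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = xp.SimConfig.from_file(path)
    assert back.to_dict() == cfg.to_dict()


def test_tn5_pwm_width_is_recognition_sequence_width():
    assert xp.TN5_PWM.shape == (xp.TN5_PWM_WIDTH, 4)
    assert xp.TN5_PWM_WIDTH == 19


# ---------------------------------------------------------------------------
# sonication


def test_lognormal_params_recover_mode_and_sd():
    mu, sigma = lognormal_params(180, 80)
    rng = np.random.default_rng(0)
    draws = rng.lognormal(mu, sigma, 400_000)
    assert abs(draws.std() - 80) < 1.5
    # mode of a lognormal is exp(mu - sigma^2)
    assert abs(math.exp(mu - sigma**2) - 180) < 1e-9


def test_fragment_sizes_within_bounds(big_genome):
    genome, sites = big_genome
    cfg = _cfg("seq", seed=2, n_fragments=10_000)
    frags = simulate_fragments(genome, sites, cfg)
    sizes = np.array([f.size for f in frags])
    assert len(frags) == 10_000
    assert sizes.min() >= cfg.frag_size_min
    assert sizes.max() <= cfg.frag_size_max


def test_background_only_fragments_carry_no_crosslinks(big_genome):
    genome, sites = big_genome
    cfg = _cfg("seq", seed=3, n_fragments=2_000, background_frac=1.0)
    frags = simulate_fragments(genome, sites, cfg)
    assert all(not f.crosslinks and f.origin_site == "background" for f in frags)


def test_site_enrichment_matches_weighted_sampling_expectation(big_genome):
    """Fraction of site-overlapping fragments matches the closed form within 3 SE."""
    genome, sites = big_genome
    sites = sites[:10]
    cfg = _cfg("seq", seed=4, n_fragments=20_000, enrichment=50.0, background_frac=0.1)
    frags = simulate_fragments(genome, sites, cfg)

    def overlaps(f):
        return any(s.start < f.end and s.end > f.start for s in sites)

    observed = sum(overlaps(f) for f in frags) / len(frags)
    # independent expectation: E[(1 - bg) * E*n_over / (E*n_over + n_non)]
    margin = cfg.read_len + cfg.stop_offset + 4
    exp_terms = []
    for f in frags:
        s = f.size
        lo, hi = margin, len(genome) - s - margin
        ov = _merged_overlap_intervals(sites, s, lo, hi)
        n_over = sum(b - a for a, b in ov)
        n_non = (hi - lo) - n_over
        q = cfg.enrichment * n_over / (cfg.enrichment * n_over + n_non)
        exp_terms.append((1 - cfg.background_frac) * q)
    expected = float(np.mean(exp_terms))
    se = math.sqrt(expected * (1 - expected) / len(frags))
    assert abs(observed - expected) < 3 * se


def test_empty_genome_rejected():
    with pytest.raises(ValueError):
        simulate_fragments("", [], _cfg("seq"))


# ---------------------------------------------------------------------------
# exonuclease geometry


def _frag(start=1000, end=1300, xl=((1150, "+"),), mid=None):
    return Fragment(
        chrom="chrS",
        start=start,
        end=end,
        origin_site="site_0000",
        origin_strand="+",
        site_mid=mid,
        crosslinks=list(xl),
    )


def test_exo_stop_coordinate_arithmetic():
    cfg = _cfg("exo5.0", p_shoulder=0.0, p_inner_site=0.0)
    rng = np.random.default_rng(0)
    geom = xp.exo_process(_frag(xl=((1150, "+"),)), cfg, rng)
    assert (geom.r1_pos5, geom.r1_strand) == (1150 - cfg.stop_offset, "+")
    assert (geom.r2_pos5, geom.r2_strand) == (1299, "-")
    geom = xp.exo_process(_frag(xl=((1150, "-"),)), cfg, rng)
    assert (geom.r1_pos5, geom.r1_strand) == (1150 + cfg.stop_offset, "-")
    assert (geom.r2_pos5, geom.r2_strand) == (1000, "+")


def test_full_shoulder_reduces_to_sonication_ends():
    cfg = _cfg("exo5.0", p_shoulder=1.0)
    rng = np.random.default_rng(1)
    for _ in range(20):
        geom = xp.exo_process(_frag(), cfg, rng)
        assert geom.shoulder
        assert geom.r1_pos5 in (1000, 1299)


def test_stop_outside_fragment_raises():
    cfg = _cfg("exo5.0", p_shoulder=0.0, p_inner_site=0.0)
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError, match="outside fragment"):
        xp.exo_process(_frag(xl=((1003, "+"),)), cfg, rng)


def test_exo_process_rejects_non_exo_versions():
    with pytest.raises(ValueError):
        xp.exo_process(_frag(), _cfg("seq"), np.random.default_rng(0))


def test_inner_stop_ligation_gates_emission():
    cfg = _cfg("exo4.0", p_shoulder=0.0, p_inner_site=1.0, p_inner_ligation=0.0)
    rng = np.random.default_rng(3)
    assert xp.exo_process(_frag(mid=1150), cfg, rng) is None
    cfg = _cfg("exo1.1", p_shoulder=0.0, p_inner_site=1.0, p_inner_ligation=1.0)
    geom = xp.exo_process(_frag(mid=1150), cfg, rng)
    assert geom.r1_pos5 == 1150  # secondary stop at the motif midpoint
    assert geom.r1_strand == "-"  # motif-complementary strand for a + site


# ---------------------------------------------------------------------------
# tagmentation


def test_tagmentation_probability_closed_form(big_genome):
    """Survival of 1-(1-p)^L: 0.634 at L=100 vs 0.951 at L=300 for p=0.01."""
    genome, _ = big_genome
    cfg = _cfg("mentation", p_tagment_per_bp=0.01, p_carry=0.0)
    rng = np.random.default_rng(5)
    for L, expect in ((100, 1 - 0.99**100), (300, 1 - 0.99**300)):
        frags = [Fragment("chrS", 1000 + i * 600, 1000 + i * 600 + L) for i in range(400)]
        kept = tagment(frags, genome, cfg, rng)
        se = math.sqrt(expect * (1 - expect) / 400)
        assert abs(len(kept) / 400 - expect) < 4 * se


def test_uniform_pwm_gives_uniform_cut_positions(big_genome):
    genome, _ = big_genome
    uniform = np.full((19, 4), 0.25)
    cfg = _cfg("mentation", tn5_pwm=uniform, p_tagment_per_bp=1.0, p_carry=0.0)
    rng = np.random.default_rng(6)
    L = 120
    start = 5_000
    frags = [Fragment("chrS", start, start + L) for _ in range(50_000)]
    kept = tagment(frags, genome, cfg, rng)
    cuts = np.array([f.cut_site for f in kept])
    # cut = window start + 9; support is [start+9, start+L-10]
    counts = np.bincount(cuts - (start + 9), minlength=L - 19 + 1)
    stat, p = chisquare(counts)
    assert p > 0.01


def test_no_carryover_when_p_carry_zero(big_genome):
    genome, sites = big_genome
    cfg = _cfg("exo3.1", seed=7, n_fragments=3_000, p_carry=0.0)
    records, truth = xp.simulate_library(genome, sites, cfg)
    assert not truth["carryover"].any()


def test_fragment_shorter_than_pwm_rejected(big_genome):
    genome, _ = big_genome
    cfg = _cfg("mentation")
    with pytest.raises(ValueError, match="shorter"):
        tagment([Fragment("chrS", 100, 110)], genome, cfg, np.random.default_rng(0))


def test_tagmentation_length_bias_raises_mean_insert(big_genome):
    """Length-weighted Tn5 selection shifts the library toward larger inserts."""
    genome, sites = big_genome
    cfg = _cfg("mentation", seed=8, n_fragments=30_000, p_carry=0.0, dup_mean=1.0)
    rng = np.random.default_rng(cfg.seed)
    frags = simulate_fragments(genome, sites, cfg, rng)
    input_mean = np.mean([f.size for f in frags])
    records, _ = xp.simulate_library(genome, sites, cfg)
    emitted = xp.insert_sizes(xp.TagSet.from_records(records))
    se = np.std(emitted) / math.sqrt(len(emitted))
    assert np.mean(emitted) > input_mean + 3 * se


# ---------------------------------------------------------------------------
# barcoding


def test_nexus_reads_carry_ctga_spacer(big_genome):
    genome, _ = big_genome
    cfg = _cfg("nexus", p_overtrim=0.0)
    rng = np.random.default_rng(9)
    geom = _Geometry(5000, "+", 5200, "-")
    rec = apply_barcode_scheme(geom, genome, cfg, rng, "m1", "chrS")
    assert rec.r1_seq[5:9] == "CTGA"
    assert len(rec.r1_seq) == cfg.read_len
    assert rec.r1_seq[9:] == genome[5000 : 5000 + cfg.read_len - 9]
    assert rec.r1_pos5 == 5000  # barcode is clipped before mapping


def test_nexus_overtrim_removes_terminal_bases_in_order(big_genome):
    genome, _ = big_genome
    cfg = _cfg("nexus", p_overtrim=1.0)  # always erodes to the cap of 4
    rng = np.random.default_rng(10)
    rec = apply_barcode_scheme(_Geometry(5000, "+", 5200, "-"), genome, cfg, rng, "m1", "chrS")
    assert rec.barcode_trim_k == 4
    assert rec.r1_seq[5:] == genome[5000 : 5000 + cfg.read_len - 5]


def test_v40_mapped_coordinate_displaced_5bp(big_genome):
    """exo4.0's random pentamer pushes the mapped stop 5 bp 5' along the read."""
    genome, _ = big_genome
    rng = np.random.default_rng(11)
    for strand, r2, expect in (("+", 5200, 5000 - 5), ("-", 4800, 5000 + 5)):
        geom = _Geometry(5000, strand, r2, "-" if strand == "+" else "+")
        rec40 = apply_barcode_scheme(geom, genome, _cfg("exo4.0"), rng, "m1", "chrS")
        rec50 = apply_barcode_scheme(geom, genome, _cfg("exo5.0"), rng, "m2", "chrS")
        assert rec40.r1_pos5 == expect
        assert rec50.r1_pos5 == 5000
        assert abs(rec40.r1_pos5 - rec50.r1_pos5) == 5


def test_read_near_chromosome_edge_rejected(big_genome):
    genome, _ = big_genome
    cfg = _cfg("exo5.0")
    with pytest.raises(ValueError, match="edge"):
        apply_barcode_scheme(
            _Geometry(len(genome) - 10, "+", len(genome) - 5, "-"),
            genome, cfg, np.random.default_rng(0), "m1", "chrS",
        )


# ---------------------------------------------------------------------------
# PCR duplication


def test_pcr_identity_at_dup_mean_one():
    cfg = _cfg("seq", dup_mean=1.0)
    recs = [xp.TagRecord(f"m{i}", "chrS", i, "+", i + 100, "-", "AC", "GT") for i in range(5)]
    assert pcr_duplicate(recs, cfg, np.random.default_rng(0)) == recs


def test_pcr_count_matches_poisson_expectation():
    cfg = _cfg("seq", dup_mean=3.0)
    recs = [xp.TagRecord(f"m{i}", "chrS", i, "+", i + 100, "-", "AC", "GT") for i in range(10_000)]
    out = pcr_duplicate(recs, cfg, np.random.default_rng(1))
    se = math.sqrt(10_000 * (cfg.dup_mean - 1))  # Var(1 + Pois(2)) = 2 per molecule
    assert abs(len(out) - 30_000) < 3 * se
    for rec in out:
        if rec.duplicate_of is not None:
            assert rec.molecule_id.startswith(rec.duplicate_of)


def test_dedupe_inverts_pcr_when_originals_distinct():
    cfg = _cfg("seq", dup_mean=2.5)
    recs = [
        xp.TagRecord(f"m{i}", "chrS", i, "+", i + 100, "-", f"A{i:04d}", f"C{i:04d}")
        for i in range(500)
    ]
    amplified = pcr_duplicate(recs, cfg, np.random.default_rng(2))
    assert len(amplified) > len(recs)
    back = xp.dedupe(xp.TagSet.from_records(amplified), mode="sequence")
    assert back.records == recs


# ---------------------------------------------------------------------------
# orchestration


def test_simulate_library_deterministic(big_genome):
    genome, sites = big_genome
    cfg = xp.SimConfig.for_version("exo5.0", seed=17, n_fragments=2_000)
    a, truth_a = xp.simulate_library(genome, sites, cfg)
    b, truth_b = xp.simulate_library(genome, sites, cfg)
    assert a == b
    assert truth_a.equals(truth_b)


def test_stop_peak_recovery_matches_configured_geometry(library_factory, big_genome):
    """Composite forward peak sits at -(crosslink_offset + stop_offset) +/- 1."""
    _, sites = big_genome
    records, _, cfg = library_factory("exo5.0", seed=17, n_fragments=50_000)
    ends = xp.five_prime_ends(xp.dedupe(xp.TagSet.from_records(records)))
    comp = xp.composite(xp.anchor_matrix(ends, sites, 100))
    same_peak, opp_peak = xp.peak_offsets(comp)
    expected = -(cfg.crosslink_offset + cfg.stop_offset)
    assert abs(same_peak - expected) <= 1
    assert abs(opp_peak - (-expected)) <= 1  # mirror stop on the other strand


def test_seq_control_has_no_stop_stripes(library_factory, big_genome):
    """ChIP-seq reads start at sonication ends: no sharp stop-site stripe."""
    _, sites = big_genome
    records, _, _ = library_factory("seq", seed=18, n_fragments=20_000, dup_mean=1.0)
    ends = xp.five_prime_ends(xp.TagSet.from_records(records))
    comp = xp.composite(xp.anchor_matrix(ends, sites, 500))
    pooled = comp.same + comp.opposite
    # the sharpest bin holds only a small share of in-window tags
    assert pooled.max() / pooled.sum() < 0.02
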