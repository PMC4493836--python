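"""iPCRess-style in-silico PCR against a brute-force oracle."""

import numpy as np
import pytest

from methamark import (
    DegenerateOligo,
    NucleotideRecord,
    PcrConfig,
    PrimerPair,
    amplify_family,
    expand,
    predict_amplicons,
    revcomp,
    scan_sites,
)


def _primer(seq, name="p", orientation="forward"):
    return DegenerateOligo(name, seq, orientation)


def _pair(fwd, rev, product, mm=2):
    return PrimerPair(
        forward=_primer(fwd, "F"), reverse=_primer(rev, "R", "reverse"),
        expected_product_bp=product, max_mismatch=mm,
    )


# ---------------------------------------------------------------------------
# scan_sites
# ---------------------------------------------------------------------------


def test_exact_site_found():
    sites = scan_sites(NucleotideRecord("t", "ACGT"), _primer("ACGT"), PcrConfig(0))
    plus = [s for s in sites if s.strand == "+"]
    assert len(plus) == 1 and (plus[0].start, plus[0].end) == (0, 4)


def test_mismatch_budget_controls_detection():
    t = NucleotideRecord("t", "ACGA")
    assert [s for s in scan_sites(t, _primer("ACGT"), PcrConfig(0, both_strands=False))] == []
    sites = scan_sites(t, _primer("ACGT"), PcrConfig(1, both_strands=False))
    assert len(sites) == 1 and sites[0].mismatches == 1


def test_degenerate_position_is_not_a_mismatch():
    sites = scan_sites(NucleotideRecord("t", "ACGT"), _primer("ACRT"), PcrConfig(0, both_strands=False))
    assert len(sites) == 1 and sites[0].mismatches == 0


def test_template_shorter_than_primer_gives_no_sites():
    assert scan_sites(NucleotideRecord("t", "ACG"), _primer("ACGTACGT"), PcrConfig(2)) == []


def test_template_n_matches_by_default_but_not_strict():
    t = NucleotideRecord("t", "ACNT")
    assert scan_sites(t, _primer("ACGT"), PcrConfig(0, both_strands=False))
    assert not scan_sites(
        t, _primer("ACGT"), PcrConfig(0, both_strands=False, strict_template_ambiguity=True)
    )


def test_three_prime_clamp():
    t = NucleotideRecord("t", "TCGTAAAA")  # mismatch at primer 5' end only
    cfg = PcrConfig(1, both_strands=False, clamp_3prime=3)
    assert scan_sites(t, _primer("ACGT"), cfg)
    t2 = NucleotideRecord("t", "ACGAAAAA")  # mismatch at primer 3' end
    assert not scan_sites(t2, _primer("ACGT"), cfg)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_sites(template, primer_seq, budget, both_strands=True):
    """Expand the primer fully and run a naive Hamming scan on both strands."""
    out = set()
    L = len(primer_seq)
    for strand, probe_pool in (
        ("+", expand(primer_seq)),
        ("-", {revcomp(s) for s in expand(primer_seq)}),
    ):
        if strand == "-" and not both_strands:
            continue
        for start in range(len(template) - L + 1):
            win = template[start : start + L]
            best = min(
                sum(a != b for a, b in zip(win, probe)) for probe in probe_pool
            )
            if best <= budget:
                out.add((strand, start, start + L, best))
    return out


@pytest.mark.parametrize("seed", range(4))
def test_scan_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    codes = list("ACGTRYWSKMDHVBN")
    for _ in range(15):
        plen = int(rng.integers(4, 13))
        primer = "".join(
            rng.choice(codes, p=[0.2] * 4 + [0.2 / 11] * 11) for _ in range(plen)
        )
        if len(expand(primer)) > 256:
            continue
        template = "".join(rng.choice(list("ACGT"), int(rng.integers(30, 300))))
        budget = int(rng.integers(0, 3))
        got = {
            (s.strand, s.start, s.end, s.mismatches)
            for s in scan_sites(
                NucleotideRecord("t", template), _primer(primer), PcrConfig(budget)
            )
        }
        assert got == brute_force_sites(template, primer, budget)


def test_mismatch_budget_monotonicity(rng):
    template = NucleotideRecord("t", "".join(rng.choice(list("ACGT"), 200)))
    primer = _primer("ACGTACGTAC")
    prev = set()
    for budget in range(4):
        cur = {(s.strand, s.start) for s in scan_sites(template, primer, PcrConfig(budget))}
        assert prev <= cur
        prev = cur


# ---------------------------------------------------------------------------
# predict_amplicons
# ---------------------------------------------------------------------------


def _template_for(pair, spacer, rng):
    fwd = sorted(expand(pair.forward.seq))[0]
    rev = revcomp(sorted(expand(pair.reverse.seq))[0])
    mid = "".join(rng.choice(list("ACGT"), spacer))
    return NucleotideRecord("t1", fwd + mid + rev)


def test_constructed_template_yields_single_clean_amplicon(primer_pairs, rng):
    pair = primer_pairs["mcrB"]
    tmpl = _template_for(pair, 300, rng)
    amps = predict_amplicons(tmpl, pair, PcrConfig(2, product_tolerance_bp=60))
    assert len(amps) == 1
    a = amps[0]
    assert a.product_bp == 334  # 17 + 300 + 17
    assert a.fwd_site.mismatches == 0 and a.rev_site.mismatches == 0
    assert a.sequence == tmpl.seq


def test_product_tolerance_boundary(primer_pairs, rng):
    pair = primer_pairs["mcrB"]
    tmpl = _template_for(pair, 300, rng)  # product 334, expected 392, |diff| = 58
    assert predict_amplicons(tmpl, pair, PcrConfig(2, product_tolerance_bp=50)) == []
    assert len(predict_amplicons(tmpl, pair, PcrConfig(2, product_tolerance_bp=60))) == 1


def test_forward_site_alone_gives_no_product(primer_pairs, rng):
    pair = primer_pairs["mcrB"]
    fwd = sorted(expand(pair.forward.seq))[0]
    tmpl = NucleotideRecord("t", fwd + "".join(rng.choice(list("ACGT"), 400)))
    assert predict_amplicons(tmpl, pair, PcrConfig(2)) == []


def test_strand_symmetry(primer_pairs, rng):
    pair = primer_pairs["mcrB"]
    tmpl = _template_for(pair, 300, rng)
    flipped = NucleotideRecord("t1", revcomp(tmpl.seq))
    cfg = PcrConfig(2, product_tolerance_bp=60)
    fwd_amps = predict_amplicons(tmpl, pair, cfg)
    rev_amps = predict_amplicons(flipped, pair, cfg)
    assert len(fwd_amps) == len(rev_amps) == 1
    assert rev_amps[0].sequence == fwd_amps[0].sequence  # reported 5'->3'
    assert rev_amps[0].strand == "-"
    assert rev_amps[0].product_bp == fwd_amps[0].product_bp


def test_missing_expected_length_rejected(primer_pairs):
    import dataclasses

    broken = dataclasses.replace(primer_pairs["mcrB"])
    broken.expected_product_bp = None
    with pytest.raises(ValueError, match="expected_product_bp"):
        predict_amplicons(NucleotideRecord("t", "ACGT" * 100), broken, PcrConfig())


# ---------------------------------------------------------------------------
# amplify_family
# ---------------------------------------------------------------------------


def test_family_with_exact_sites_has_full_coverage(primer_pairs, rng):
    pair = primer_pairs["mtaB"]
    fam = [_template_for(pair, 400, rng) for _ in range(10)]
    for i, rec in enumerate(fam):
        rec.id = f"m{i}"
    table, coverage = amplify_family(fam, pair, PcrConfig(2))
    assert coverage == 1.0
    assert (table.n_amplicons >= 1).all()


def test_members_with_three_mismatches_drop_out(primer_pairs, rng):
    pair = primer_pairs["mtaB"]
    fam = []
    for i in range(10):
        rec = _template_for(pair, 400, rng)
        rec.id = f"m{i}"
        if i < 3:  # plant 3 mismatches in the forward site
            s = list(rec.seq)
            for pos in (2, 7, 12):
                s[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
            rec.seq = "".join(s)
        fam.append(rec)
    _, coverage = amplify_family(fam, pair, PcrConfig(2, product_tolerance_bp=60))
    assert coverage == pytest.approx(0.7)


def test_empty_family_reports_zero_coverage(primer_pairs, caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        table, coverage = amplify_family([], primer_pairs["mcrB"], PcrConfig())
    assert coverage == 0.0 and table.empty
    assert any("empty family" in r.message for r in caplog.records)
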