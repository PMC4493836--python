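"""In-silico PCR: predict amplicons from degenerate primer pairs.

Binding sites are found by a positional Hamming scan (no indels) in
which an IUPAC-compatible primer/template position counts as a match
(zero mismatch cost).  A product is called when both primers bind on
opposite strands, the sites do not overlap, and the product length is
within a tolerance of the pair's expected length — the same rule used
to screen the published marker primers against complete genomes (two
mismatches per primer, ±50 nt product tolerance; four mismatches for
the longer mcrG primers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .primer_design import PrimerPair
from .seqcore import DegenerateOligo, NucleotideRecord, encode_mask, revcomp

logger = logging.getLogger(__name__)


@dataclass
class PcrConfig:
    max_mismatch_per_primer: int = 2
    product_tolerance_bp: int = 50
    both_strands: bool = True
    strict_template_ambiguity: bool = False
    clamp_3prime: int = 0  # require 0 mismatches in the last N primer bases

    def __post_init__(self):
        if min(self.max_mismatch_per_primer, self.product_tolerance_bp, self.clamp_3prime) < 0:
            raise ValueError("PCR config values must be non-negative")


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    strand: str  # '+' or '-'
    start: int  # 0-based half-open, + strand coordinates
    end: int
    mismatches: int
    primer_name: str


@dataclass
class Amplicon:
    template_id: str
    fwd_site: BindingSite
    rev_site: BindingSite
    product_bp: int
    sequence: str
    strand: str = "+"


# ---------------------------------------------------------------------------
# Site scanning
# ---------------------------------------------------------------------------


def _mismatch_profile(primer_mask: np.ndarray, template_mask: np.ndarray, strict: bool) -> np.ndarray:
    """Per-offset mismatch counts of primer against every template window."""
    L = len(primer_mask)
    if len(template_mask) < L:
        return np.zeros(0, dtype=int)
    wins = sliding_window_view(template_mask, L)
    if strict:
        mm = (wins & ~primer_mask[None, :]) != 0
    else:
        mm = (wins & primer_mask[None, :]) == 0
    return mm.sum(axis=1)


def _scan_one_strand(
    template: NucleotideRecord,
    oligo_seq: str,
    primer_name: str,
    strand: str,
    cfg: PcrConfig,
) -> list[BindingSite]:
    pm = encode_mask(oligo_seq)
    tm = encode_mask(template.seq)
    mm = _mismatch_profile(pm, tm, cfg.strict_template_ambiguity)
    sites = []
    L = len(oligo_seq)
    hits = np.nonzero(mm <= cfg.max_mismatch_per_primer)[0]
    if cfg.clamp_3prime > 0 and hits.size:
        # 3' end of the primer: rightmost bases on '+', leftmost on '-'
        k = min(cfg.clamp_3prime, L)
        seg = pm[-k:] if strand == "+" else pm[:k]
        off = L - k if strand == "+" else 0
        tmw = sliding_window_view(tm, L)
        kept = []
        for s in hits:
            w = tmw[s, off : off + k]
            bad = ((w & ~seg) != 0) if cfg.strict_template_ambiguity else ((w & seg) == 0)
            if not bad.any():
                kept.append(s)
        hits = np.array(kept, dtype=int)
    for s in hits:
        s = int(s)
        sites.append(
            BindingSite(
                template_id=template.id,
                strand=strand,
                start=s,
                end=s + L,
                mismatches=int(mm[s]),
                primer_name=primer_name,
            )
        )
    return sites


def scan_sites(
    template: NucleotideRecord, primer: DegenerateOligo, cfg: PcrConfig | None = None
) -> list[BindingSite]:
    """All primer binding sites on the template within the mismatch budget.

    Sites are reported in + strand coordinates; a '-' strand site means
    the primer binds the reverse complement there.  A template shorter
    than the primer yields no sites.
    """
    cfg = cfg or PcrConfig()
    sites = _scan_one_strand(template, primer.seq, primer.name, "+", cfg)
    if cfg.both_strands:
        rc = revcomp(primer.seq)
        sites += _scan_one_strand(template, rc, primer.name, "-", cfg)
    return sorted(sites, key=lambda s: (s.start, s.strand))


# ---------------------------------------------------------------------------
# Amplicon prediction
# ---------------------------------------------------------------------------


def predict_amplicons(
    templates: list[NucleotideRecord] | NucleotideRecord,
    pair: PrimerPair,
    cfg: PcrConfig | None = None,
) -> list[Amplicon]:
    """Products where both primers bind convergently within the length
    tolerance.  Both template orientations are considered; amplicon
    sequences are reported 5'->3' starting at the forward primer."""
    cfg = cfg or PcrConfig(max_mismatch_per_primer=pair.max_mismatch)
    if pair.expected_product_bp is None:
        raise ValueError("PrimerPair.expected_product_bp must be set before prediction")
    if isinstance(templates, NucleotideRecord):
        templates = [templates]
    out: list[Amplicon] = []
    for tmpl in templates:
        fwd_sites = scan_sites(tmpl, pair.forward, cfg)
        rev_sites = scan_sites(tmpl, pair.reverse, cfg)
        # + orientation: forward on '+', reverse on '-', reverse site downstream
        for f in (s for s in fwd_sites if s.strand == "+"):
            for r in (s for s in rev_sites if s.strand == "-"):
                if r.start < f.end:
                    continue  # overlapping primers -> no product
                product = r.end - f.start
                if abs(product - pair.expected_product_bp) > cfg.product_tolerance_bp:
                    continue
                out.append(
                    Amplicon(
                        template_id=tmpl.id,
                        fwd_site=f,
                        rev_site=r,
                        product_bp=product,
                        sequence=tmpl.seq[f.start : r.end],
                        strand="+",
                    )
                )
        if cfg.both_strands:
            # - orientation: forward primer on '-', reverse primer on '+'
            for f in (s for s in fwd_sites if s.strand == "-"):
                for r in (s for s in rev_sites if s.strand == "+"):
                    if f.start < r.end:
                        continue
                    product = f.end - r.start
                    if abs(product - pair.expected_product_bp) > cfg.product_tolerance_bp:
                        continue
                    out.append(
                        Amplicon(
                            template_id=tmpl.id,
                            fwd_site=f,
                            rev_site=r,
                            product_bp=product,
                            sequence=revcomp(tmpl.seq[r.start : f.end]),
                            strand="-",
                        )
                    )
    out.sort(key=lambda a: (a.template_id, min(a.fwd_site.start, a.rev_site.start), a.strand))
    return out


def amplify_family(
    family: list[NucleotideRecord], pair: PrimerPair, cfg: PcrConfig | None = None
) -> tuple[pd.DataFrame, float]:
    """Per-sequence amplification table and family coverage.

    Coverage is the fraction of family members yielding at least one
    amplicon — a direct measure of the primer pair's inclusivity over a
    gene family.  An empty family reports coverage 0 with a warning.
    """
    cfg = cfg or PcrConfig(max_mismatch_per_primer=pair.max_mismatch)
    if not family:
        logger.warning("amplify_family called with an empty family; coverage undefined, reporting 0")
        return (
            pd.DataFrame(columns=["template_id", "n_amplicons", "best_product_bp", "fwd_mm", "rev_mm"]),
            0.0,
        )
    rows = []
    n_hit = 0
    for rec in sorted(family, key=lambda r: r.id):
        amps = predict_amplicons(rec, pair, cfg)
        if amps:
            n_hit += 1
            best = min(amps, key=lambda a: a.fwd_site.mismatches + a.rev_site.mismatches)
            rows.append(
                {
                    "template_id": rec.id,
                    "n_amplicons": len(amps),
                    "best_product_bp": best.product_bp,
                    "fwd_mm": best.fwd_site.mismatches,
                    "rev_mm": best.rev_site.mismatches,
                }
            )
        else:
            rows.append(
                {
                    "template_id": rec.id,
                    "n_amplicons": 0,
                    "best_product_bp": pd.NA,
                    "fwd_mm": pd.NA,
                    "rev_mm": pd.NA,
                }
            )
    return pd.DataFrame(rows), n_hit / len(family)


def amplicon_table(amplicons: list[Amplicon], one_based: bool = False) -> pd.DataFrame:
    """Tabular amplicon report (0-based half-open by default; 1-based
    inclusive with ``one_based=True`` for cross-checks against iPCRess)."""
    rows = []
    for a in amplicons:
        start = min(a.fwd_site.start, a.rev_site.start)
        end = max(a.fwd_site.end, a.rev_site.end)
        rows.append(
            {
                "template_id": a.template_id,
                "strand": a.strand,
                "start": start + 1 if one_based else start,
                "end": end if one_based else end,
                "product_bp": a.product_bp,
                "fwd_mm": a.fwd_site.mismatches,
                "rev_mm": a.rev_site.mismatches,
            }
        )
    return pd.DataFrame(
        rows, columns=["template_id", "strand", "start", "end", "product_bp", "fwd_mm", "rev_mm"]
    )
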