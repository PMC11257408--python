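"""C-to-U edit-candidate calling from pileup tables.

The caller is a depth-thresholded one-sided exact binomial test of the
alternate-base count against a uniform per-base sequencing-error floor:
at a reference C, the U count is tested against Binomial(depth, e/3),
where ``e`` is the total substitution rate and the division by 3 spreads
it over the non-reference bases. A site is called when depth strictly
exceeds the minimum (default 10) and the upper-tail p-value falls below
alpha (default 0.05). This is a declared simplification of
quality-aware low-frequency variant callers: base qualities are not
modelled, and no multiple-testing correction is applied at this stage —
replicate concordance downstream is the de facto error control.

In strand-aware mode G-to-A events are also tested; they are oriented to
the canonical C>U label by :func:`orient_strand` once transcript strand
is known.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class VariantCall:
    """A candidate edit event at one pileup site."""

    ref_name: str
    position: int          # 0-based
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int
    f: float               # alt_count / depth
    p_value: float
    oriented_edit: str     # e.g. "C>U" after strand mapping; raw label before

    @property
    def edit(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"


def compute_site_frequency(counts: dict[str, int] | pd.Series, alt_base: str) -> float:
    """Alternate-base frequency alt_count/depth for one site."""
    depth = int(counts["A"]) + int(counts["C"]) + int(counts["G"]) + int(counts["U"])
    if depth == 0:
        raise ValueError("frequency undefined at zero depth")
    return int(counts[alt_base]) / depth


def binomial_upper_tail(alt_count: int, depth: int, rate: float) -> float:
    """P(X >= alt_count) for X ~ Binomial(depth, rate), exact."""
    if alt_count <= 0:
        return 1.0
    return float(stats.binom.sf(alt_count - 1, depth, rate))


def call_c_to_u(pileup: pd.DataFrame, error_rate: float,
                min_depth: int = 10, alpha: float = 0.05,
                strand_aware: bool = False) -> list[VariantCall]:
    """Call C>U (and, when strand-aware, G>A) candidates from one pileup.

    ``min_depth`` is exclusive: a site needs depth strictly greater than
    it to be eligible.
    """
    if not 0.0 < error_rate < 0.25:
        raise ValueError("error_rate must be in (0, 0.25)")
    per_alt_rate = error_rate / 3.0
    pairs = [("C", "U")] + ([("G", "A")] if strand_aware else [])
    calls: list[VariantCall] = []
    for row in pileup.itertuples(index=False):
        if row.depth <= min_depth:
            continue
        for ref_base, alt_base in pairs:
            if row.refbase != ref_base:
                continue
            alt_count = int(getattr(row, alt_base))
            p = binomial_upper_tail(alt_count, int(row.depth), per_alt_rate)
            if p < alpha:
                calls.append(VariantCall(
                    ref_name=row.ref, position=int(row.pos),
                    ref_base=ref_base, alt_base=alt_base,
                    depth=int(row.depth), alt_count=alt_count,
                    f=alt_count / int(row.depth), p_value=p,
                    oriented_edit=f"{ref_base}>{alt_base}",
                ))
    return calls


def orient_strand(call: VariantCall, feature_strand: str | None):
    """Map a raw call onto transcript orientation.

    Returns ``(oriented call or None, reason)``. A C>U on the plus
    strand passes through; a G>A on the minus strand is the same
    chemistry read on the opposite strand and is relabelled C>U. Calls
    inconsistent with either orientation are dropped with a reason;
    unknown strand routes the call to an "unoriented" bucket rather
    than silently discarding it.
    """
    edit = call.edit
    if feature_strand is None:
        return replace(call, oriented_edit="unoriented"), "unknown strand"
    if feature_strand == "+" and edit == "C>U":
        return replace(call, oriented_edit="C>U"), None
    if feature_strand == "-" and edit == "G>A":
        return replace(call, oriented_edit="C>U"), None
    return None, f"{edit} inconsistent with strand {feature_strand!r}"


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    """VCF-like TSV layout (positions 1-based for human-readable output)."""
    return pd.DataFrame([{
        "ref": c.ref_name, "pos": c.position + 1, "refbase": c.ref_base,
        "alt": c.alt_base, "depth": c.depth, "alt_count": c.alt_count,
        "f": c.f, "p": c.p_value, "oriented": c.oriented_edit,
    } for c in calls])
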