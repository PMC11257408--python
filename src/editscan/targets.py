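"""Cross-sample candidate-target filtering, tiering and annotation.

A candidate depletion-sensitive site must first be detected in every
replicate of every condition (replicate intersection); it is then kept
only if editing drops after knockdown under one of two concordance
rules, both used in practice on different transcript classes:

``all_replicates_decrease``
    every individual knockdown-replicate frequency lies below the
    control-condition mean (the per-replicate rule applied to the
    pre-rRNA site set);
``mean_decrease``
    each knockdown condition's mean frequency lies below the control
    mean (the rule applied transcriptome-wide).

Retained sites carry a percent difference
``100 * (f_control - f_kd) / f_control``, with the knockdown summary
being the unweighted mean over knockdown-condition means, and are
tiered at strict >33% and >66% change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .seq import ReferenceSequence
from .synth import StudyDesign
from .variants import VariantCall


class ConcordanceMode(str, Enum):
    ALL_REPLICATES_DECREASE = "all_replicates_decrease"
    MEAN_DECREASE = "mean_decrease"


@dataclass
class CandidateSite:
    ref_name: str
    position: int                                  # 0-based
    oriented_edit: str
    f_by_replicate: dict[tuple[str, int], float]
    f_control_mean: float = float("nan")
    f_kd_means: dict[str, float] = field(default_factory=dict)
    percent_difference: float = float("nan")
    tier: str = "all"                              # "all" | "gt33" | "gt66"
    uc_motif: bool | None = None
    context: str | None = None
    region: str | None = None
    gene: str | None = None


def intersect_replicates(
    calls: dict[tuple[str, int], list[VariantCall]],
) -> list[CandidateSite]:
    """Sites called in every replicate of every sample, with the full
    frequency matrix attached."""
    if not calls:
        return []
    units = sorted(calls.keys())
    indexed = {
        unit: {(c.ref_name, c.position, c.oriented_edit): c for c in unit_calls}
        for unit, unit_calls in calls.items()
    }
    keys = set(indexed[units[0]])
    for unit in units[1:]:
        keys &= set(indexed[unit])
    sites = []
    for ref_name, position, edit in sorted(keys):
        f_by_rep = {
            unit: indexed[unit][(ref_name, position, edit)].f for unit in units
        }
        sites.append(CandidateSite(ref_name, position, edit, f_by_rep))
    return sites


def percent_difference(f_control: float, f_kd: float) -> float:
    """Percent drop in editing relative to control: 100*(fc - fkd)/fc."""
    if f_control <= 0:
        raise ValueError("percent difference undefined for f_control <= 0")
    return 100.0 * (f_control - f_kd) / f_control


def classify_targets(sites: list[CandidateSite], design: StudyDesign,
                     mode: ConcordanceMode | str) -> list[CandidateSite]:
    """Apply the knockdown-decrease concordance rule and compute percent
    differences for the survivors."""
    mode = ConcordanceMode(mode)
    kept = []
    for site in sites:
        ctrl = [f for (s, _), f in site.f_by_replicate.items()
                if s == design.control_label]
        if len(ctrl) < design.replicates_per_sample:
            raise ValueError(
                f"site {site.position}: incomplete control frequencies"
            )
        ctrl_mean = float(np.mean(ctrl))
        kd_means = {}
        ok = True
        for kd in design.kd_labels:
            reps = [f for (s, _), f in site.f_by_replicate.items() if s == kd]
            if len(reps) < design.replicates_per_sample:
                raise ValueError(f"site {site.position}: incomplete {kd} frequencies")
            kd_means[kd] = float(np.mean(reps))
            if mode is ConcordanceMode.ALL_REPLICATES_DECREASE:
                ok = ok and all(f < ctrl_mean for f in reps)
            else:
                ok = ok and kd_means[kd] < ctrl_mean
        if not ok:
            continue
        site.f_control_mean = ctrl_mean
        site.f_kd_means = kd_means
        kd_summary = float(np.mean(list(kd_means.values())))
        site.percent_difference = percent_difference(ctrl_mean, kd_summary)
        kept.append(site)
    return kept


def tier_sites(sites: list[CandidateSite]) -> list[CandidateSite]:
    """Label tiers at strict >33% and >66% edit change."""
    for site in sites:
        pd_ = site.percent_difference
        if pd_ > 66.0:
            site.tier = "gt66"
        elif pd_ > 33.0:
            site.tier = "gt33"
        else:
            site.tier = "all"
    return sites


def annotate_context(site: CandidateSite, ref: ReferenceSequence,
                     flank: int = 10) -> CandidateSite:
    """Attach the +/- flank sequence window and the UC-motif flag (true
    iff the base immediately upstream of the edited C is U)."""
    site.context = ref.context(site.position, flank=flank)
    site.uc_motif = (site.position > 0
                     and ref.sequence[site.position - 1] == "U")
    return site


def annotate_region(site: CandidateSite, annotation: AnnotationSet) -> CandidateSite:
    region, gene = annotation.region_of(site.ref_name, site.position)
    site.region = region
    site.gene = gene
    return site


def sites_to_frame(sites: list[CandidateSite]) -> pd.DataFrame:
    """One row per candidate site; one column per replicate frequency."""
    rows = []
    for s in sites:
        row = {"ref": s.ref_name, "pos": s.position + 1, "edit": s.oriented_edit}
        for (sample, rep), f in sorted(s.f_by_replicate.items()):
            row[f"f_{sample}_r{rep}"] = f
        row.update({
            "f_control_mean": s.f_control_mean,
            "percent_difference": s.percent_difference,
            "tier": s.tier, "uc_motif": s.uc_motif,
            "region": s.region, "gene": s.gene,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def sites_to_bed(sites: list[CandidateSite]) -> str:
    """BED lines (0-based half-open) for the called sites."""
    return "\n".join(
        f"{s.ref_name}\t{s.position}\t{s.position + 1}\t{s.oriented_edit}"
        for s in sites
    ) + ("\n" if sites else "")
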