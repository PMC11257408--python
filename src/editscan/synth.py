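"""Synthetic study generator.

Emulates the data layout of a replicated nuclear RNA-seq editing study:
an RNA reference with C-to-U edit sites planted at known frequencies, a
control condition and one or more knockdown conditions in which the edit
frequency drops by a known factor, duplicate replicates per condition,
and per-site pileup tables produced by binomial/multinomial read
sampling over a uniform sequencing-error floor. A companion set of
generators produces transcript annotations with gene-set memberships,
high-content screen wells (per-cell nucleolus counts), and per-nucleus
DNA-intensity populations with G1/G2 structure.

Defaults mirror the study conditions the downstream statistics assume:
planted edit frequencies spanning roughly 0.3-25%, two knockdown
conditions at half the control frequency, two replicates per condition,
an error floor of 1e-3 per base, and screen controls separated as in the
published assay (about 19% one-nucleolus cells in negative controls,
29% in positive controls).

Every generator is deterministic given its seed; replicate-level draws
are decorrelated through a seed hierarchy (master seed + sample and
replicate indices), so a study regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq import RNA_BASES, Feature, ReferenceSequence
from .annotation import AnnotationSet, Transcript

#: Planted-site edit-frequency range, matching the span observed at
#: depletion-sensitive sites on the pre-rRNA (0.34%-23.39%).
DEFAULT_F_CONTROL_RANGE = (0.0034, 0.2339)
DEFAULT_ERROR_RATE = 1e-3
#: One-nucleolus fractions printed for the published screen controls.
DEFAULT_NEG_FRACTION = 0.192
DEFAULT_POS_FRACTION = 0.292

PILEUP_COLUMNS = ["ref", "pos", "refbase", "A", "C", "G", "U", "depth"]


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one edited cytidine."""

    position: int
    f_control: float
    f_kd: dict[str, float]
    uc_context: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_control <= 1.0:
            raise ValueError("f_control must be in [0, 1]")
        for label, f in self.f_kd.items():
            if not 0.0 <= f <= self.f_control:
                raise ValueError(
                    f"knockdown frequency for {label!r} must be in [0, f_control]"
                )


@dataclass(frozen=True)
class StudyDesign:
    """Condition x replicate layout. The study design is duplicate
    replicates of one control and two knockdown conditions."""

    control_label: str = "control"
    kd_labels: tuple[str, ...] = ("kd_pool", "kd_single")
    replicates_per_sample: int = 2

    def __post_init__(self) -> None:
        labels = (self.control_label, *self.kd_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        if not self.kd_labels:
            raise ValueError("at least one knockdown condition required")
        if self.replicates_per_sample < 2:
            raise ValueError("at least 2 replicates per sample required")

    @property
    def samples(self) -> tuple[str, ...]:
        return (self.control_label, *self.kd_labels)

    def units(self) -> list[tuple[str, int]]:
        """All (sample, replicate) units, replicates numbered from 1."""
        return [(s, r + 1) for s in self.samples
                for r in range(self.replicates_per_sample)]


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def generate_reference(length: int, base_probs=(0.25, 0.25, 0.25, 0.25),
                       seed: int = 0, name: str = "synthetic") -> ReferenceSequence:
    """I.i.d. RNA sequence with the given A/C/G/U composition."""
    if length < 2:
        raise ValueError("length must be >= 2")
    p = np.asarray(base_probs, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("base_probs must be a non-negative 4-vector summing to 1")
    rng = _rng(seed, 0)
    bases = rng.choice(list(RNA_BASES), size=length, p=p / p.sum())
    return ReferenceSequence(name, "".join(bases))


def plant_edit_sites(ref: ReferenceSequence, n_sites: int,
                     f_control_range: tuple[float, float] = DEFAULT_F_CONTROL_RANGE,
                     kd_reduction: float | dict[str, float] = 0.5,
                     kd_labels: tuple[str, ...] = ("kd_pool", "kd_single"),
                     require_uc: bool = False, min_spacing: int = 2,
                     seed: int = 0) -> list[PlantedSite]:
    """Choose edited cytidines and assign true frequencies.

    Control frequencies are drawn uniformly from ``f_control_range``;
    each knockdown condition edits at ``f_control * (1 - reduction)``.
    Sites are kept at least ``min_spacing`` nt apart so their motif
    contexts stay independent.
    """
    if isinstance(kd_reduction, dict):
        reductions = dict(kd_reduction)
    else:
        reductions = {label: float(kd_reduction) for label in kd_labels}
    for label, r in reductions.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"kd_reduction for {label!r} must be in [0, 1]")

    eligible = ref.uc_positions() if require_uc else ref.positions_of("C")
    rng = _rng(seed, 1)
    order = rng.permutation(len(eligible))
    chosen: list[int] = []
    for idx in order:
        pos = eligible[idx]
        if all(abs(pos - q) >= min_spacing for q in chosen):
            chosen.append(pos)
        if len(chosen) == n_sites:
            break
    if len(chosen) < n_sites:
        kind = "UC-context C" if require_uc else "C"
        raise ValueError(
            f"cannot plant {n_sites} sites with spacing >= {min_spacing}: "
            f"only {len(chosen)} of {len(eligible)} eligible {kind} positions usable"
        )
    lo, hi = f_control_range
    sites = []
    for pos in sorted(chosen):
        f_control = float(rng.uniform(lo, hi))
        f_kd = {label: f_control * (1.0 - r) for label, r in reductions.items()}
        uc = pos > 0 and ref.sequence[pos - 1] == "U"
        sites.append(PlantedSite(pos, f_control, f_kd, uc))
    return sites


def _site_probs(ref_base: str, f: float, error_rate: float) -> np.ndarray:
    """Per-read base probabilities at a site edited at frequency f.

    A read reports the edited base (U) with probability f; any read is
    then misread to each of the other 3 bases at error_rate/3.
    """
    e = error_rate
    p = np.full(4, e / 3.0)
    i_ref = RNA_BASES.index(ref_base)
    i_u = RNA_BASES.index("U")
    p[i_ref] = (1.0 - f) * (1.0 - e) + f * (e / 3.0)
    p[i_u] = f * (1.0 - e) + (1.0 - f) * (e / 3.0)
    if i_ref == i_u:  # unedited U reference
        p[i_ref] = 1.0 - e
    return p


def simulate_pileups(ref: ReferenceSequence, planted: list[PlantedSite],
                     design: StudyDesign, depth: int = 1000,
                     error_rate: float = DEFAULT_ERROR_RATE,
                     seed: int = 0) -> dict[tuple[str, int], pd.DataFrame]:
    """Per-(sample, replicate) pileup tables over every reference position.

    Non-planted positions see each non-reference base at error_rate/3;
    planted positions add the condition's true edit frequency on U.
    Counts at a site always sum to ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    by_pos = {s.position: s for s in planted}
    for s in planted:
        if ref.sequence[s.position] != "C":
            raise ValueError(f"planted site {s.position} is not a C in the reference")

    n = len(ref)
    tables: dict[tuple[str, int], pd.DataFrame] = {}
    for si, sample in enumerate(design.samples):
        for rep in range(1, design.replicates_per_sample + 1):
            rng = _rng(seed, 2, si, rep)
            counts = np.zeros((n, 4), dtype=int)
            for pos in range(n):
                base = ref.sequence[pos]
                f = 0.0
                site = by_pos.get(pos)
                if site is not None:
                    f = (site.f_control if sample == design.control_label
                         else site.f_kd[sample])
                counts[pos] = rng.multinomial(depth, _site_probs(base, f, error_rate))
            df = pd.DataFrame({
                "ref": ref.name,
                "pos": np.arange(n),
                "refbase": list(ref.sequence),
                "A": counts[:, 0], "C": counts[:, 1],
                "G": counts[:, 2], "U": counts[:, 3],
                "depth": counts.sum(axis=1),
            })
            tables[(sample, rep)] = df
    return tables


def generate_annotation(ref: ReferenceSequence, n_genes: int,
                        set_baselines: dict[str, float] | None = None,
                        frac_coding: float = 0.8, frac_minus: float = 0.4,
                        seed: int = 0) -> AnnotationSet:
    """Pack non-overlapping transcripts onto the reference.

    Each transcript gets 2-4 exons with introns between them; coding
    transcripts get terminal UTRs carved from the first and last exon.
    Gene-set membership is Bernoulli at each set's baseline fraction
    (e.g. ``{"nucleolar": 0.177, "TP53_target": 0.008}``).
    """
    set_baselines = set_baselines or {}
    for name, b in set_baselines.items():
        if not 0.0 <= b <= 1.0:
            raise ValueError(f"baseline for set {name!r} must be in [0, 1]")
    rng = _rng(seed, 3)
    n = len(ref)
    min_len = 40
    if n_genes * (min_len + 5) > n:
        raise ValueError(
            f"cannot pack {n_genes} transcripts of >= {min_len} nt into {n} nt"
        )
    # split the reference into n_genes slots with small random gaps
    bounds = np.linspace(0, n, n_genes + 1).astype(int)
    transcripts = []
    for g in range(n_genes):
        gene = f"gene{g + 1:04d}"
        lo, hi = int(bounds[g]), int(bounds[g + 1])
        start = lo + int(rng.integers(0, max(1, (hi - lo - min_len) // 4)))
        end = hi - int(rng.integers(1, max(2, (hi - lo - min_len) // 4)))
        strand = "-" if rng.random() < frac_minus else "+"
        coding = bool(rng.random() < frac_coding)
        n_exons = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(start + 2, end - 2), size=2 * n_exons - 2,
                                  replace=False))
        edges = [start, *cuts.tolist(), end]
        exons = [(edges[2 * i], edges[2 * i + 1]) for i in range(n_exons)]
        exons = [(s, e) for s, e in exons if e > s]
        utr5 = utr3 = None
        if coding and len(exons) >= 2:
            s0, e0 = exons[0]
            s1, e1 = exons[-1]
            left = (s0, min(e0, s0 + max(1, (e0 - s0) // 3)))
            right = (max(s1, e1 - max(1, (e1 - s1) // 3)), e1)
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
        transcripts.append(Transcript(
            gene=gene, ref_name=ref.name, start=start, end=end, strand=strand,
            exons=exons, coding=coding, utr5=utr5, utr3=utr3,
        ))
    gene_sets = {
        name: {t.gene for t in transcripts if rng.random() < baseline}
        for name, baseline in set_baselines.items()
    }
    return AnnotationSet(transcripts, gene_sets)


def simulate_screen_wells(n_neg: int, n_pos: int,
                          treatments: dict[str, float] | None = None,
                          cells_per_well: int = 3000,
                          neg_fraction: float = DEFAULT_NEG_FRACTION,
                          pos_fraction: float = DEFAULT_POS_FRACTION,
                          seed: int = 0) -> pd.DataFrame:
    """Wells of per-cell nucleolus counts for the nucleolar-number assay.

    Each cell harbours 1 nucleolus with the well's true fraction, else 2
    or 3 (equally likely), emulating the published 2-3 nucleoli norm.
    Returns a long table ``well treatment role cell nucleoli``.
    """
    if cells_per_well < 1:
        raise ValueError("cells_per_well must be >= 1")
    treatments = treatments or {}
    for label, frac in treatments.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"one-nucleolus fraction for {label!r} must be in [0, 1]")
    wells = (
        [(f"neg{i + 1:02d}", "siNT", "negative", neg_fraction) for i in range(n_neg)]
        + [(f"pos{i + 1:02d}", "siPOS", "positive", pos_fraction) for i in range(n_pos)]
        + [(f"test_{label}", label, "test", frac)
           for label, frac in sorted(treatments.items())]
    )
    frames = []
    for wi, (well, treatment, role, frac) in enumerate(wells):
        rng = _rng(seed, 4, wi)
        one = rng.random(cells_per_well) < frac
        multi = rng.integers(2, 4, size=cells_per_well)
        counts = np.where(one, 1, multi)
        frames.append(pd.DataFrame({
            "well": well, "treatment": treatment, "role": role,
            "cell": np.arange(cells_per_well), "nucleoli": counts,
        }))
    return pd.concat(frames, ignore_index=True)


PHASES = ("sub-G1", "G1", "S", "G2/M", ">4n")


def simulate_dna_intensities(phase_fractions, n_cells: int = 10000,
                             cv: float = 0.05, g1_log2_center: float = 10.0,
                             seed: int = 0) -> np.ndarray:
    """Raw per-nucleus integrated DNA intensities with cell-cycle structure.

    G1 nuclei centre at ``2**g1_log2_center`` and G2/M at twice that (one
    log2 unit up); S-phase nuclei spread uniformly between the peaks;
    sub-G1 falls below G1 and >4n above G2/M. Multiplicative log-normal
    noise with the given coefficient of variation is applied throughout.
    """
    p = np.asarray(phase_fractions, dtype=float)
    if p.shape != (5,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("phase_fractions must be a non-negative 5-vector summing to 1")
    if not 0.0 <= cv < 0.3:
        raise ValueError("cv must be in [0, 0.3)")
    rng = _rng(seed, 5)
    phase = rng.choice(5, size=n_cells, p=p)
    x0 = g1_log2_center
    # positions in normalized units (G1 = 1, G2 = 2), mapped to raw log2
    v = np.empty(n_cells)
    v[phase == 0] = rng.uniform(0.35, 0.70, size=(phase == 0).sum())   # sub-G1
    v[phase == 1] = 1.0                                                 # G1
    v[phase == 2] = rng.uniform(1.30, 1.70, size=(phase == 2).sum())   # S
    v[phase == 3] = 2.0                                                 # G2/M
    v[phase == 4] = rng.uniform(2.60, 3.20, size=(phase == 4).sum())   # >4n
    log2_int = x0 + (v - 1.0)
    if cv > 0:
        sigma_log2 = np.sqrt(np.log1p(cv ** 2)) / np.log(2)
        log2_int = log2_int + rng.normal(0.0, sigma_log2, size=n_cells)
    return np.power(2.0, log2_int)


def preribosome_reference(seed: int = 0, length: int = 13400) -> ReferenceSequence:
    """A mock 47S-like pre-rRNA: random sequence with the canonical
    5'ETS / 18S / ITS1 / 5.8S / ITS2 / 28S / 3'ETS segmentation laid out
    proportionally to the human precursor."""
    ref = generate_reference(length, seed=seed, name="pre47S_synthetic")
    # proportional layout of the human 47S segments
    spans = [("5'ETS", 0.00, 0.27), ("18S", 0.27, 0.41), ("ITS1", 0.41, 0.49),
             ("5.8S", 0.49, 0.50), ("ITS2", 0.50, 0.58), ("28S", 0.58, 0.965),
             ("3'ETS", 0.965, 1.00)]
    ref.features = [
        Feature(label, int(a * length), int(b * length)) for label, a, b in spans
    ]
    return ref
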