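"""High-content nucleolar-screen statistics.

Covers four readouts of a 384-well siRNA screen for ribosome-biogenesis
regulators:

* **One-nucleolus percent effect** — the fraction of cells harbouring a
  single nucleolus, rescaled so the negative control (non-targeting
  siRNA) sits at 0% and the positive control at 100%. Effects are
  computed per replicate and averaged; hits require a mean effect at or
  above +3 standard deviations of the negative-control well effects.
* **5-EU percent inhibition** — nucleolar nascent-RNA signal rescaled
  between negative (0%) and transcription-blocked positive (100%)
  controls; the magnitude classifies the mechanism (``> 80`` pre-rRNA
  transcription, ``50-80`` processing/maturation, ``< 50`` not required
  for ribosome biogenesis).
* **Cell-cycle binning** — per-nucleus integrated DNA intensities are
  log2-transformed and normalised so the control G1 peak is 1.0 and the
  G2 peak 2.0, then binned: sub-G1 < 0.75, G1 [0.75, 1.25), S
  [1.25, 1.75), G2/M [1.75, 2.5], >4n > 2.5.
* **RAMP** (ratio analysis of multiple precursors) — each pre-rRNA
  processing intermediate's abundance relative to its upstream
  precursor, expressed as a log2 fold change versus the control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synth import PHASES

CELL_CYCLE_BOUNDS = (0.75, 1.25, 1.75, 2.5)


def one_nucleolus_fraction(nucleoli_counts: Sequence[int]) -> float:
    """Fraction of cells with exactly one nucleolus."""
    counts = np.asarray(nucleoli_counts)
    if counts.size == 0:
        raise ValueError("no cells in well")
    return float(np.mean(counts == 1))


def percent_effect(x_test: float, x_neg: float, x_pos: float) -> float:
    """Rescale a well summary so the negative control is 0% and the
    positive control 100%."""
    if x_pos == x_neg:
        raise ValueError("degenerate controls: positive equals negative")
    return 100.0 * (x_test - x_neg) / (x_pos - x_neg)


def mean_percent_effect(x_test_by_rep: Mapping[int, float],
                        x_neg_by_rep: Mapping[int, float],
                        x_pos_by_rep: Mapping[int, float]) -> float:
    """Per-replicate percent effect, averaged across replicates."""
    effects = [percent_effect(x_test_by_rep[r], x_neg_by_rep[r], x_pos_by_rep[r])
               for r in x_test_by_rep]
    return float(np.mean(effects))


def call_hits(effects_by_replicate: Mapping[str, Mapping[int, float]],
              neg_well_effects: Mapping[int, Sequence[float]],
              n_sd: float = 3.0) -> dict[str, dict]:
    """Hit calling at +3 SD above the negative control.

    Parameters
    ----------
    effects_by_replicate:
        treatment -> {replicate -> percent effect}.
    neg_well_effects:
        replicate -> percent effects of the individual negative-control
        wells of that replicate (>= 2 wells required). Their standard
        deviation sets the replicate's threshold ``n_sd * SD``.

    A treatment is a hit when its mean effect across replicates is at
    or above the mean of the per-replicate thresholds (``>=``, so a
    treatment sitting exactly at 3 SD is a hit). Per-replicate pass
    flags are returned alongside. With identical negative wells
    (SD = 0) any positive mean effect is a hit.
    """
    thresholds = {}
    for rep, effects in neg_well_effects.items():
        effects = np.asarray(effects, dtype=float)
        if effects.size < 2:
            raise ValueError(f"replicate {rep}: need >= 2 negative-control wells")
        thresholds[rep] = n_sd * float(np.std(effects, ddof=1))
    mean_threshold = float(np.mean(list(thresholds.values())))
    out = {}
    for treatment, by_rep in effects_by_replicate.items():
        mean_effect = float(np.mean(list(by_rep.values())))
        per_rep = {rep: eff >= thresholds[rep] for rep, eff in by_rep.items()}
        if mean_threshold == 0.0:
            hit = mean_effect > 0.0 or any(per_rep.values())
        else:
            hit = mean_effect >= mean_threshold
        out[treatment] = {
            "mean_effect": mean_effect, "hit": hit,
            "threshold": mean_threshold, "per_replicate": per_rep,
        }
    return out


def percent_inhibition(eu_test: float, eu_neg: float, eu_pos: float) -> tuple[float, str]:
    """5-EU percent inhibition and its mechanistic class.

    I = 100 * (neg - test) / (neg - pos); class boundaries at 50 and 80
    separate factors not required for ribosome biogenesis, processing/
    maturation factors, and transcription(-and-processing) factors.
    """
    if eu_neg == eu_pos:
        raise ValueError("degenerate controls: positive equals negative")
    inhibition = 100.0 * (eu_neg - eu_test) / (eu_neg - eu_pos)
    if inhibition > 80.0:
        cls = "transcription"
    elif inhibition >= 50.0:
        cls = "processing/maturation"
    else:
        cls = "not required"
    return inhibition, cls


def _kde_peaks(log2_values: np.ndarray, bandwidth: float,
               grid_points: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density on a grid; returns (grid, density)."""
    lo = log2_values.min() - 4 * bandwidth
    hi = log2_values.max() + 4 * bandwidth
    grid = np.linspace(lo, hi, grid_points)
    # explicit Gaussian KDE with a fixed, physically meaningful bandwidth
    diffs = (grid[:, None] - log2_values[None, :]) / bandwidth
    density = np.exp(-0.5 * diffs ** 2).sum(axis=1)
    return grid, density


def locate_g1_g2_peaks(control_intensities: Sequence[float],
                       bandwidth: float = 0.05,
                       g2_offset_tol: float = 0.3) -> tuple[float, float]:
    """G1 and G2 peak positions (log2) of a control DNA-intensity population.

    The G1 peak is the global mode of a Gaussian-smoothed histogram of
    log2 intensities; the G2 peak is the highest local maximum one log2
    unit above G1 (within ``+/- g2_offset_tol``), reflecting the 2-fold
    DNA content of G2/M nuclei.
    """
    values = np.log2(np.asarray(control_intensities, dtype=float))
    grid, density = _kde_peaks(values, bandwidth)
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    peak_idx = np.where(interior)[0] + 1
    if peak_idx.size < 2:
        raise ValueError(
            "fewer than 2 modes in the control DNA-intensity histogram; "
            "cannot anchor G1 and G2 peaks"
        )
    peaks = grid[peak_idx]
    heights = density[peak_idx]
    g1 = float(peaks[np.argmax(heights)])
    window = np.abs(peaks - (g1 + 1.0)) <= g2_offset_tol
    if not window.any():
        raise ValueError(
            "no candidate G2 peak within one log2 unit (+/- "
            f"{g2_offset_tol}) above the G1 peak in the control histogram"
        )
    g2_candidates = peaks[window]
    g2 = float(g2_candidates[np.argmax(heights[window])])
    return g1, g2


def normalize_dna_intensity(raw_intensities: Sequence[float],
                            control_intensities: Sequence[float],
                            bandwidth: float = 0.05) -> np.ndarray:
    """Map log2 DNA intensities so the control G1 peak is 1.0 and the G2
    peak is 2.0; the affine map from the control is applied to all
    samples sharing its staining scale."""
    g1, g2 = locate_g1_g2_peaks(control_intensities, bandwidth=bandwidth)
    values = np.log2(np.asarray(raw_intensities, dtype=float))
    return 1.0 + (values - g1) / (g2 - g1)


def bin_cell_cycle(normalized_values: Sequence[float]) -> dict[str, float]:
    """Phase fractions from normalised log2 DNA content.

    Bins: sub-G1 < 0.75, G1 [0.75, 1.25), S [1.25, 1.75),
    G2/M [1.75, 2.5], >4n > 2.5. Every cell lands in exactly one bin.
    """
    v = np.asarray(normalized_values, dtype=float)
    if v.size == 0:
        raise ValueError("no cells to bin")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite normalized intensities")
    b = CELL_CYCLE_BOUNDS
    counts = {
        "sub-G1": int(np.sum(v < b[0])),
        "G1": int(np.sum((v >= b[0]) & (v < b[1]))),
        "S": int(np.sum((v >= b[1]) & (v < b[2]))),
        "G2/M": int(np.sum((v >= b[2]) & (v <= b[3]))),
        ">4n": int(np.sum(v > b[3])),
    }
    assert sum(counts.values()) == v.size
    return {phase: counts[phase] / v.size for phase in PHASES}


@dataclass(frozen=True)
class RampPathway:
    """Ordered precursor -> product edges of a processing pathway,
    e.g. 47S -> 45S -> 32S -> 12S on the large-subunit route."""

    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        species = self.species
        # reject cycles: each product must appear after its precursor
        seen: set[str] = set()
        order: list[str] = []
        for u, d in self.edges:
            for s in (u, d):
                if s not in seen:
                    seen.add(s)
                    order.append(s)
        rank = {s: i for i, s in enumerate(order)}
        for u, d in self.edges:
            if rank[d] <= rank[u] and (d, u) in self.edges:
                raise ValueError(f"cycle between {u} and {d}")
        if len(species) < 2:
            raise ValueError("pathway needs at least 2 species")

    @property
    def species(self) -> tuple[str, ...]:
        out: list[str] = []
        for u, d in self.edges:
            for s in (u, d):
                if s not in out:
                    out.append(s)
        return tuple(out)

    @classmethod
    def from_chain(cls, species: Iterable[str]) -> "RampPathway":
        species = list(species)
        return cls(tuple((species[i], species[i + 1])
                         for i in range(len(species) - 1)))


#: ITS2-probe-detectable species on the human LSU maturation route.
LSU_PATHWAY = RampPathway.from_chain(["47S", "45S", "32S", "12S"])


def ramp_log2fc(intensities_test: Mapping[str, float],
                intensities_control: Mapping[str, float],
                pathway: RampPathway = LSU_PATHWAY) -> dict[str, float]:
    """Log2 fold change of each product/precursor ratio versus control.

    For edge (precursor u, product d):
    ``log2[(d_test / u_test) / (d_control / u_control)]``. A positive
    value means the product accumulates relative to its precursor in
    the test sample; the signature of a processing block at u -> d is a
    positive value on the upstream edge and a negative one downstream.
    """
    missing = [s for s in pathway.species
               if intensities_test.get(s, 0) <= 0 or intensities_control.get(s, 0) <= 0]
    if missing:
        raise ValueError(f"non-positive or missing intensities for: {missing}")
    out = {}
    for u, d in pathway.edges:
        ratio_test = intensities_test[d] / intensities_test[u]
        ratio_ctrl = intensities_control[d] / intensities_control[u]
        out[f"{d}/{u}"] = float(np.log2(ratio_test / ratio_ctrl))
    return out
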