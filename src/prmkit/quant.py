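"""Chromatographic peak detection and stable-isotope-dilution quantification.

Input is a long-format table of extracted-ion chromatograms (XICs): one
time/intensity row per sample, peptide, isotope channel (light = endogenous,
heavy = SIL spike) and fragment.  For each sample/peptide the workflow is:

1. detect one peak group per channel (summed fragment trace, smoothed,
   apex above a signal-to-noise threshold, valley/fraction-of-apex
   boundaries, trapezoidal fragment areas);
2. apply the coelution criterion — the endogenous peak must share
   retention time with its SIL counterpart (apex distance within a
   tolerance AND sufficient boundary overlap), otherwise the peptide is
   not considered detected in that run;
3. for detected peptides, compute the light-to-heavy peak-area ratio, the
   relative abundance measure (higher ratio = more endogenous peptide,
   given a fixed SIL spike).

Undetected peptides yield *absent* ratios, never zeros: a zero would
fabricate signal in downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "XicTrace",
    "PeakGroup",
    "QuantResult",
    "QuantConfig",
    "detect_peak",
    "coelution_test",
    "light_heavy_ratio",
    "quantify",
    "call_detection",
    "read_xic_tsv",
    "results_to_frame",
]

XIC_COLUMNS = ["sample_id", "peptide", "channel", "fragment", "time_min", "intensity"]


@dataclass(frozen=True)
class XicTrace:
    """One fragment's extracted-ion chromatogram."""

    sample_id: str
    peptide: str
    channel: str  # "light" | "heavy"
    fragment_label: str
    times: np.ndarray  # minutes, strictly increasing
    intensities: np.ndarray  # nonnegative

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities must have equal length")
        if len(self.times) < 5:
            raise ValueError("need >= 5 chromatographic points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class PeakGroup:
    peptide: str
    channel: str
    apex_time: float
    boundaries: tuple[float, float]
    area: float
    fragment_areas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.boundaries
        if not (lo < self.apex_time < hi):
            raise ValueError("apex must lie strictly inside the boundaries")
        if self.area < 0:
            raise ValueError("area must be nonnegative")


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    peptide: str
    coelutes: bool
    detected: bool
    light_to_heavy_ratio: float | None
    apex_delta: float | None


@dataclass
class QuantConfig:
    """Peak-picking and coelution thresholds.

    ``apex_tolerance`` (min) and ``min_overlap`` (fraction of the shorter
    peak) encode the coelution criterion; defaults 0.1 min / 0.5.
    """

    smooth_window: int = 5
    snr_threshold: float = 5.0
    boundary_fraction: float = 0.01
    apex_tolerance: float = 0.1
    min_overlap: float = 0.5


def _common_grid(traces: Sequence[XicTrace]) -> np.ndarray:
    first = traces[0].times
    if all(
        len(t.times) == len(first) and np.allclose(t.times, first) for t in traces[1:]
    ):
        return np.asarray(first, dtype=float)
    lo = max(t.times[0] for t in traces)
    hi = min(t.times[-1] for t in traces)
    step = min(np.min(np.diff(t.times)) for t in traces)
    return np.arange(lo, hi + step / 2, step)


def _background_subtracted_area(
    y: np.ndarray, grid: np.ndarray, sel: slice
) -> float:
    # per-fragment background = median of the full trace (the peak occupies
    # a minority of the window); negative residuals are clipped
    background = float(np.median(y))
    resid = np.clip(y[sel] - background, 0.0, None)
    return float(np.trapezoid(resid, grid[sel]))


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="same")


def detect_peak(
    traces: Sequence[XicTrace], config: QuantConfig | None = None
) -> PeakGroup | None:
    """Pick the dominant peak from a set of fragment XICs, or ``None``.

    The fragment traces are resampled to a shared grid if needed, summed
    and smoothed with a moving average.  The apex is the global maximum;
    it must clear ``snr_threshold`` times the robust noise level (MAD of
    the summed trace) above baseline.  Boundaries extend from the apex to
    the nearest valley or to where intensity falls below
    ``boundary_fraction`` of apex height above baseline.  Each fragment is
    then integrated by the trapezoid rule over those boundaries.
    """
    cfg = config or QuantConfig()
    traces = list(traces)
    if not traces:
        return None
    grid = _common_grid(traces)
    frag_y = {}
    for t in traces:
        if len(grid) == len(t.times) and np.allclose(grid, t.times):
            frag_y[t.fragment_label] = np.asarray(t.intensities, dtype=float)
        else:
            frag_y[t.fragment_label] = np.interp(grid, t.times, t.intensities)
    total = np.sum(list(frag_y.values()), axis=0)
    if not np.any(total > 0):
        return None
    smoothed = _smooth(total, cfg.smooth_window)
    apex_idx = int(np.argmax(smoothed))
    apex_height = smoothed[apex_idx]
    baseline = float(np.median(smoothed))
    noise = 1.4826 * float(np.median(np.abs(smoothed - baseline)))
    floor = max(noise, 1e-12)
    if (apex_height - baseline) / floor < cfg.snr_threshold:
        return None
    cutoff = baseline + cfg.boundary_fraction * (apex_height - baseline)
    lo = apex_idx
    while lo > 0 and smoothed[lo - 1] <= smoothed[lo] and smoothed[lo - 1] > cutoff:
        lo -= 1
    hi = apex_idx
    last = len(smoothed) - 1
    while hi < last and smoothed[hi + 1] <= smoothed[hi] and smoothed[hi + 1] > cutoff:
        hi += 1
    if lo == apex_idx:
        lo = max(apex_idx - 1, 0)
    if hi == apex_idx:
        hi = min(apex_idx + 1, last)
    sel = slice(lo, hi + 1)
    fragment_areas = {
        label: _background_subtracted_area(y, grid, sel)
        for label, y in frag_y.items()
    }
    return PeakGroup(
        peptide=traces[0].peptide,
        channel=traces[0].channel,
        apex_time=float(grid[apex_idx]),
        boundaries=(float(grid[lo]), float(grid[hi])),
        area=float(sum(fragment_areas.values())),
        fragment_areas=fragment_areas,
    )


def coelution_test(
    light: PeakGroup | None,
    heavy: PeakGroup | None,
    apex_tolerance: float = 0.1,
    min_overlap: float = 0.5,
) -> tuple[bool, float | None]:
    """Do the endogenous and SIL peaks share retention time?

    True iff the apex distance is within ``apex_tolerance`` (closed
    boundary: a delta exactly at tolerance passes) AND the boundary
    intervals overlap by at least ``min_overlap`` of the shorter one.
    Either peak absent -> (False, None): peptides whose peaks do not
    coelute with their SIL counterparts are excluded.
    """
    if light is None or heavy is None:
        return False, None
    delta = abs(light.apex_time - heavy.apex_time)
    lo = max(light.boundaries[0], heavy.boundaries[0])
    hi = min(light.boundaries[1], heavy.boundaries[1])
    overlap = max(0.0, hi - lo)
    shorter = min(
        light.boundaries[1] - light.boundaries[0],
        heavy.boundaries[1] - heavy.boundaries[0],
    )
    ok = delta <= apex_tolerance and shorter > 0 and overlap / shorter >= min_overlap
    return ok, delta


def light_heavy_ratio(light: PeakGroup, heavy: PeakGroup) -> float:
    """Endogenous over SIL peak area; proportional to endogenous amount."""
    if heavy.area <= 0:
        raise ValueError(
            f"heavy (SIL) area is zero for {heavy.peptide}: spike missing, "
            "ratio undefined"
        )
    return light.area / heavy.area


def _integrate_over(
    traces: Sequence[XicTrace], boundaries: tuple[float, float], peptide: str, channel: str
) -> PeakGroup | None:
    grid = _common_grid(list(traces))
    lo, hi = boundaries
    mask = (grid >= lo) & (grid <= hi)
    if mask.sum() < 2:
        return None
    sel = slice(int(np.argmax(mask)), int(len(mask) - np.argmax(mask[::-1])))
    fragment_areas = {}
    for t in traces:
        y = np.interp(grid, t.times, t.intensities)
        fragment_areas[t.fragment_label] = _background_subtracted_area(y, grid, sel)
    total = np.sum(
        [np.interp(grid, t.times, t.intensities) for t in traces], axis=0
    )
    sub = total[mask]
    apex_idx = int(np.argmax(sub))
    apex_t = float(grid[mask][apex_idx])
    if not (lo < apex_t < hi):
        # apex on the boundary: nudge inside by half a grid step
        apex_t = min(max(apex_t, np.nextafter(lo, hi)), np.nextafter(hi, lo))
    return PeakGroup(
        peptide=peptide,
        channel=channel,
        apex_time=apex_t,
        boundaries=(lo, hi),
        area=float(sum(fragment_areas.values())),
        fragment_areas=fragment_areas,
    )


def quantify_pair(
    light_traces: Sequence[XicTrace],
    heavy_traces: Sequence[XicTrace],
    config: QuantConfig | None = None,
) -> QuantResult:
    """Full per-run quantification of one peptide.

    Peak boundaries for the ratio are taken from the heavy channel when
    both peaks exist: the SIL spike is uniform across samples, so its
    boundaries are the more reproducible integration window.
    """
    cfg = config or QuantConfig()
    sample_id = (light_traces or heavy_traces)[0].sample_id
    peptide = (light_traces or heavy_traces)[0].peptide
    light_peak = detect_peak(light_traces, cfg) if light_traces else None
    heavy_peak = detect_peak(heavy_traces, cfg) if heavy_traces else None
    coelutes, delta = coelution_test(
        light_peak, heavy_peak, cfg.apex_tolerance, cfg.min_overlap
    )
    if not coelutes:
        return QuantResult(sample_id, peptide, coelutes, False, None, delta)
    light_in_window = _integrate_over(
        light_traces, heavy_peak.boundaries, peptide, "light"
    )
    if light_in_window is None or heavy_peak.area <= 0:
        return QuantResult(sample_id, peptide, coelutes, False, None, delta)
    ratio = light_heavy_ratio(light_in_window, heavy_peak)
    return QuantResult(sample_id, peptide, coelutes, True, ratio, delta)


def _traces_from_frame(df: pd.DataFrame) -> list[XicTrace]:
    out = []
    for (sample, pep, channel, frag), sub in df.groupby(
        ["sample_id", "peptide", "channel", "fragment"], sort=True
    ):
        sub = sub.sort_values("time_min")
        out.append(
            XicTrace(
                sample_id=str(sample),
                peptide=str(pep),
                channel=str(channel),
                fragment_label=str(frag),
                times=sub["time_min"].to_numpy(dtype=float),
                intensities=sub["intensity"].to_numpy(dtype=float),
            )
        )
    return out


def quantify(
    xic: pd.DataFrame,
    peptides: Iterable[str] | None = None,
    config: QuantConfig | None = None,
) -> list[QuantResult]:
    """Quantify every (sample, peptide) pair in a long-format XIC table.

    If a ``replicate`` column is present, replicates are quantified
    separately and averaged at the ratio level (detected iff any
    replicate is detected).  Panel peptides absent from the table come
    back as undetected results so presence tables stay complete.
    """
    cfg = config or QuantConfig()
    missing = [c for c in XIC_COLUMNS if c not in xic.columns]
    if missing:
        raise ValueError(f"XIC table lacks columns: {missing}")
    has_reps = "replicate" in xic.columns
    results: list[QuantResult] = []
    samples = sorted(xic["sample_id"].astype(str).unique())
    for sample in samples:
        sdf = xic[xic["sample_id"].astype(str) == sample]
        for pep, pdf in sdf.groupby("peptide", sort=True):
            per_rep: list[QuantResult] = []
            rep_keys = sorted(pdf["replicate"].unique()) if has_reps else [None]
            for rep in rep_keys:
                rdf = pdf if rep is None else pdf[pdf["replicate"] == rep]
                traces = _traces_from_frame(rdf)
                light = [t for t in traces if t.channel == "light"]
                heavy = [t for t in traces if t.channel == "heavy"]
                per_rep.append(quantify_pair(light, heavy, cfg))
            detected = [r for r in per_rep if r.detected]
            if detected:
                ratio = float(np.mean([r.light_to_heavy_ratio for r in detected]))
                delta = float(np.mean([r.apex_delta for r in detected]))
                results.append(
                    QuantResult(sample, str(pep), True, True, ratio, delta)
                )
            else:
                deltas = [r.apex_delta for r in per_rep if r.apex_delta is not None]
                results.append(
                    QuantResult(
                        sample,
                        str(pep),
                        any(r.coelutes for r in per_rep),
                        False,
                        None,
                        float(np.mean(deltas)) if deltas else None,
                    )
                )
    if peptides is not None:
        seen = {(r.sample_id, r.peptide) for r in results}
        for sample in samples:
            for pep in peptides:
                if (sample, pep) not in seen:
                    results.append(QuantResult(sample, pep, False, False, None, None))
    results.sort(key=lambda r: (r.sample_id, r.peptide))
    return results


def results_to_frame(results: Sequence[QuantResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "peptide": [r.peptide for r in results],
            "coelutes": [r.coelutes for r in results],
            "detected": [r.detected for r in results],
            "light_to_heavy_ratio": [r.light_to_heavy_ratio for r in results],
            "apex_delta": [r.apex_delta for r in results],
        }
    )


def call_detection(
    results: Sequence[QuantResult],
    sample_groups: Mapping[str, str],
    peptides: Sequence[str],
    peptide_proteins: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Presence/absence table: '+' iff the peptide passed coelution-gated
    detection in at least one sample of the group.

    Rows are peptides (with an optional protein column), columns the
    group labels in first-appearance order.
    """
    groups: list[str] = []
    for g in sample_groups.values():
        if g not in groups:
            groups.append(g)
    calls = {pep: {g: "-" for g in groups} for pep in peptides}
    for r in results:
        if not r.detected:
            continue
        g = sample_groups.get(r.sample_id)
        if g is None or r.peptide not in calls:
            continue
        calls[r.peptide][g] = "+"
    data = {
        "peptide": list(peptides),
        **{g: [calls[p][g] for p in peptides] for g in groups},
    }
    df = pd.DataFrame(data)
    if peptide_proteins:
        df.insert(0, "protein", [peptide_proteins.get(p, "") for p in peptides])
    return df


def read_xic_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in XIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"XIC table {path} lacks columns: {missing}")
    return df
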