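"""Stable-isotope enrichment from isotopologue intensity vectors.

Percent enrichment of a metabolite fed an n-heavy-atom substrate is
defined as the labeled intensity fraction of the sample minus that of an
unlabeled control:

    enrichment% = 100 * ( f_label(sample) - f_label(control) )

where f_label sums intensities at the label mass shifts and divides by the
total.  This difference convention is exactly 0 for an unlabeled sample
and 100 for a fully labeled one, and subtracting the control corrects the
natural-abundance contribution at the label shifts.  Values may be
slightly negative under noise; they are clipped only in reporting, never
in the arithmetic.  Intensities are pre-integrated isotopologue peak
areas; no raw spectrum processing happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IsotopologueSpectrum",
    "EnrichmentResult",
    "labeled_fraction",
    "percent_enrichment",
    "replicate_stats",
    "summarize_enrichment",
    "read_spectra_tsv",
    "write_enrichment_tsv",
    "default_shift_set",
]


@dataclass(frozen=True)
class IsotopologueSpectrum:
    """Intensity vector indexed by nominal mass shift k (intensity of M+k)."""

    sample_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 1-d vector")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite and nonnegative")
        if not np.any(arr > 0):
            raise ValueError("spectrum has no positive intensity")
        object.__setattr__(self, "intensities", arr)

    def __len__(self) -> int:
        return self.intensities.size


@dataclass(frozen=True)
class EnrichmentResult:
    """Mean +/- SD percent enrichment over replicates for one substrate."""

    substrate: str
    label_shift: int
    replicates: tuple[float, ...]
    mean: float
    sd: float


def default_shift_set(label_shift: int, n_shifts: int,
                      partial: bool = False) -> frozenset[int]:
    """Shift set for an n-heavy-atom substrate: all shifts >= n (so the
    whole shifted envelope is captured); with ``partial`` the
    partial-incorporation shifts 1..n-1 are included too."""
    lo = 1 if partial else label_shift
    return frozenset(range(lo, n_shifts))


def labeled_fraction(s: IsotopologueSpectrum, shift_set: Iterable[int]) -> float:
    """Fraction of total intensity found at the given mass shifts."""
    shifts = sorted(set(shift_set))
    if not shifts:
        raise ValueError("shift_set must be non-empty")
    if shifts[0] < 0 or shifts[-1] >= len(s):
        raise ValueError(
            f"shift_set {shifts} outside spectrum index range 0..{len(s) - 1}"
        )
    total = float(s.intensities.sum())
    return float(s.intensities[shifts].sum() / total)


def percent_enrichment(
    sample: IsotopologueSpectrum,
    control: IsotopologueSpectrum,
    shift_set: Iterable[int],
) -> float:
    """Percent enrichment of ``sample`` over an unlabeled ``control``."""
    if len(sample) != len(control):
        raise ValueError(
            f"index ranges differ: sample 0..{len(sample) - 1}, "
            f"control 0..{len(control) - 1}"
        )
    return 100.0 * (labeled_fraction(sample, shift_set) - labeled_fraction(control, shift_set))


def replicate_stats(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator)."""
    if not values:
        raise ValueError("need at least one replicate for a mean")
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, float("nan")
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
    return mean, sd


def summarize_enrichment(
    samples: Sequence[IsotopologueSpectrum],
    controls: Sequence[IsotopologueSpectrum],
    shift_set: Iterable[int],
    substrate: str = "",
    label_shift: int = 0,
) -> EnrichmentResult:
    """Per-replicate enrichment plus mean +/- SD.

    ``samples`` and ``controls`` pair up positionally; with a single
    control it is reused for every sample replicate.
    """
    if not samples:
        raise ValueError("no sample spectra")
    if len(controls) == 1:
        controls = list(controls) * len(samples)
    if len(controls) != len(samples):
        raise ValueError("controls must number one, or one per sample replicate")
    reps = tuple(
        percent_enrichment(s, c, shift_set) for s, c in zip(samples, controls)
    )
    mean, sd = replicate_stats(reps)
    return EnrichmentResult(
        substrate=substrate, label_shift=label_shift,
        replicates=reps, mean=mean, sd=sd,
    )


def read_spectra_tsv(path: str | Path) -> dict[tuple[str, str], IsotopologueSpectrum]:
    """Read spectra from a long-form TSV (sample_id, replicate, shift,
    intensity); returns one spectrum per (sample_id, replicate)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample_id": str, "replicate": str})
    required = {"sample_id", "replicate", "shift", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[tuple[str, str], IsotopologueSpectrum] = {}
    for (sid, rep), grp in df.groupby(["sample_id", "replicate"], sort=True):
        k_max = int(grp["shift"].max())
        vec = np.zeros(k_max + 1)
        vec[grp["shift"].astype(int).to_numpy()] = grp["intensity"].to_numpy()
        out[(sid, rep)] = IsotopologueSpectrum(sample_id=f"{sid}:{rep}", intensities=vec)
    return out


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Per-replicate rows plus a summary row per substrate; negative
    per-replicate values are reported clipped at 0 in a separate column."""
    with open(path, "w") as fh:
        fh.write("substrate\treplicate\tenrichment_pct\tenrichment_pct_clipped\n")
        for r in results:
            for i, v in enumerate(r.replicates, start=1):
                fh.write(f"{r.substrate}\t{i}\t{v:.4f}\t{max(v, 0.0):.4f}\n")
            fh.write(f"{r.substrate}\tmean\t{r.mean:.4f}\t{max(r.mean, 0.0):.4f}\n")
            fh.write(f"{r.substrate}\tsd\t{r.sd:.4f}\t{r.sd:.4f}\n")
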