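"""Fluctuation-assay mutation-rate estimation from plate colony counts.

Replicate cultures are grown, plated on selective medium, and the mutant
colonies on each plate counted. Under the Luria-Delbruck picture the number
of mutational *events* per culture is Poisson with mean m, so the fraction
p0 of plates with zero colonies estimates e^{-m} regardless of how large
each mutant clone grew: rate = -ln(p0) (the p0 method). Jackpot plates make
the colony-count distribution overdispersed (variance-to-mean ratio >> 1),
which is why only p0 and rank tests — never Poisson statistics on the raw
counts — are used for inference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluctuationDataset",
    "P0Result",
    "p0_rate",
    "vmr",
    "compare_samples",
    "relative_rate",
    "read_fluctuation_tsv",
]


@dataclass
class FluctuationDataset:
    """Colony counts per plate for one strain."""

    strain: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.size < 1:
            raise ValueError("need at least one plate")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("colony counts must be integers")
            arr = arr.astype(int)
        if (arr < 0).any():
            raise ValueError("colony counts must be non-negative")
        self.counts = arr

    @property
    def n_plates(self) -> int:
        return len(self.counts)

    @property
    def p0(self) -> float:
        return float((self.counts == 0).mean())


@dataclass
class P0Result:
    strain: str
    p0: float
    rate: float
    ci_low: float
    ci_high: float
    n_plates: int

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "p0": self.p0,
            "rate": self.rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_plates": self.n_plates,
        }


def _p0_point(counts: np.ndarray) -> float:
    p0 = float((counts == 0).mean())
    return -np.log(p0) if p0 > 0 else np.nan


def p0_rate(
    data: FluctuationDataset, n_boot: int = 1000, seed: int | None = None
) -> P0Result:
    """Mutation rate per culture by the p0 method: rate = -ln(p0).

    The confidence interval is a plate-level percentile bootstrap
    (``n_boot`` resamples). p0 = 0 (no zero-count plates) is an error: the
    rate is not estimable by this method. p0 = 1 returns rate 0 with a
    warning (no mutants observed at all).
    """
    p0 = data.p0
    if p0 == 0:
        raise ValueError(
            f"strain {data.strain!r}: no zero-count plates; rate not estimable "
            "by the p0 method"
        )
    if p0 == 1:
        warnings.warn(f"strain {data.strain!r}: all plates zero, rate estimated 0")
    rate = float(-np.log(p0))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, data.n_plates, size=(n_boot, data.n_plates))
    boot = np.array([_p0_point(data.counts[i]) for i in idx])
    boot = boot[np.isfinite(boot)]
    if boot.size:
        lo, hi = np.percentile(boot, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return P0Result(data.strain, p0, rate, float(lo), float(hi), data.n_plates)


def vmr(data: FluctuationDataset) -> float:
    """Variance-to-mean ratio of plate colony counts (sample variance, ddof=1).

    Much greater than 1 indicates jackpots: mutations arose during liquid
    growth, not on the plate. Mean 0 -> NaN with a warning.
    """
    mean = data.counts.mean()
    if mean == 0:
        warnings.warn(f"strain {data.strain!r}: mean count 0, VMR undefined")
        return float("nan")
    if data.n_plates < 2:
        warnings.warn(f"strain {data.strain!r}: single plate, VMR undefined")
        return float("nan")
    return float(data.counts.var(ddof=1) / mean)


def compare_samples(a: Sequence[float], b: Sequence[float], alternative: str = "less") -> float:
    """One-tailed Mann-Whitney U p-value (exact for small samples without
    ties, normal approximation with tie correction otherwise).

    ``alternative='less'`` tests a stochastically smaller than b ("a<b");
    ``'greater'`` the reverse.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.pvalue)


def relative_rate(
    variant: FluctuationDataset,
    reference: FluctuationDataset,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Ratio of p0-method rates, variant / reference, with a plate-level
    bootstrap percentile interval."""
    rv = p0_rate(variant, n_boot=0, seed=seed)
    rr = p0_rate(reference, n_boot=0, seed=seed)
    if rr.rate == 0:
        raise ValueError("reference rate is 0; relative rate undefined")
    ratio = rv.rate / rr.rate
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bv = _p0_point(variant.counts[rng.integers(0, variant.n_plates, variant.n_plates)])
        br = _p0_point(reference.counts[rng.integers(0, reference.n_plates, reference.n_plates)])
        if np.isfinite(bv) and np.isfinite(br) and br > 0:
            boots.append(bv / br)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return float(ratio), (float(lo), float(hi))


def read_fluctuation_tsv(path) -> dict[str, FluctuationDataset]:
    """Read a ``strain  plate_id  colonies`` TSV into per-strain datasets."""
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    required = {"strain", "plate_id", "colonies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fluctuation table missing columns: {sorted(missing)}")
    return {
        strain: FluctuationDataset(strain, grp["colonies"].to_numpy())
        for strain, grp in df.groupby("strain", sort=True)
    }
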