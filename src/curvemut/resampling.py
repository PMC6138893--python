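"""Permutation nulls for the mutation-landscape analyses.

Two bespoke nulls:

* :func:`dispersion_test` — are observed per-site mutation counts more
  dispersed than a uniform random assignment of the same number of mutations
  over the same sites (non-Poisson landscape)?
* :func:`context_matched_null` — is the mean site-centred curvature of
  observed mutation sites lower than that of random pseudo-sites sharing the
  same k-nucleotide sequence context elsewhere in the genome?

Empirical p-values are reported both raw (fraction of null replicates at
least as extreme, inclusive) and with the add-one correction
(b + 1)/(n_perm + 1); the corrected value is the downstream default, so an
observation beyond all 1000 nulls reports p = 1/1001.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .shape import DinucleotidePropertyTable, site_profile

__all__ = [
    "PermutationResult",
    "ContextIndex",
    "empirical_p",
    "dispersion_test",
    "build_context_index",
    "context_matched_null",
    "region_restricted_null",
]


@dataclass
class PermutationResult:
    """Observed statistic, null replicate values, tail and empirical p."""

    observed: float
    null: np.ndarray
    tail: str  # "lower" | "upper"
    p_raw: float
    p: float  # add-one corrected
    seed: int | None
    n_perm: int
    statistic: str = ""

    def __post_init__(self) -> None:
        self.null = np.asarray(self.null, dtype=float)
        if len(self.null) != self.n_perm:
            raise ValueError("null length does not match n_perm")
        if not 0 < self.p <= 1:
            raise ValueError(f"corrected p={self.p} outside (0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "tail": self.tail,
            "p_raw": self.p_raw,
            "p": self.p,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_mean": float(self.null.mean()),
            "null_sd": float(self.null.std(ddof=1)) if self.n_perm > 1 else float("nan"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def null_to_tsv(self, path) -> None:
        pd.DataFrame({"replicate": np.arange(self.n_perm), "value": self.null}).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def empirical_p(observed: float, nulls: np.ndarray, tail: str) -> tuple[float, float]:
    """(raw, add-one corrected) empirical p.

    Raw = fraction of null values <= observed (lower tail) or >= observed
    (upper tail), inclusive; corrected = (b + 1)/(n + 1). Ties are detected
    with a small relative tolerance so that statistics recomputed along
    different floating-point summation orders still count as equal.
    """
    nulls = np.asarray(nulls, dtype=float)
    n = len(nulls)
    if n == 0:
        raise ValueError("empty null distribution")
    eps = 1e-9 * max(1.0, abs(observed))
    if tail == "lower":
        b = int((nulls <= observed + eps).sum())
    elif tail == "upper":
        b = int((nulls >= observed - eps).sum())
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return b / n, min(1.0, (b + 1) / (n + 1))


def dispersion_test(
    n_sites: int,
    observed_counts: Sequence[int],
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test for over-dispersion of per-site mutation counts.

    The statistic is the sample standard deviation (ddof=1) of per-site
    counts. Each null replicate assigns the N = sum(counts) observed
    mutations uniformly at random (multinomial) to the ``n_sites`` sites;
    the p-value is upper-tail.
    """
    counts = np.asarray(observed_counts, dtype=int)
    if n_sites < 2:
        raise ValueError("dispersion test needs at least 2 sites")
    if len(counts) != n_sites:
        raise ValueError("observed_counts length must equal n_sites")
    total = int(counts.sum())
    if total < 1:
        raise ValueError("need at least one observed mutation")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(counts.std(ddof=1))
    rng = np.random.default_rng(seed)
    null = rng.multinomial(total, np.full(n_sites, 1.0 / n_sites), size=n_perm)
    null_sd = null.std(axis=1, ddof=1)
    p_raw, p = empirical_p(observed, null_sd, "upper")
    return PermutationResult(
        observed=observed,
        null=null_sd,
        tail="upper",
        p_raw=p_raw,
        p=p,
        seed=seed,
        n_perm=n_perm,
        statistic="per-site count SD",
    )


@dataclass
class ContextIndex:
    """Map from a centred k-mer context to the genome positions carrying it.

    Only positions with a complete k-mer and a complete ``flank``-bp flank on
    both sides are indexed; contexts containing ambiguous bases are excluded.
    """

    k: int
    flank: int
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __contains__(self, context: str) -> bool:
        return context in self.positions

    def __getitem__(self, context: str) -> np.ndarray:
        return self.positions[context]

    @property
    def n_positions(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))


def build_context_index(genome: str, k: int = 3, flank: int = 50) -> ContextIndex:
    """Index every eligible position of ``genome`` by its centred k-mer."""
    if k % 2 != 1:
        raise ValueError("k must be odd (centred context)")
    half = k // 2
    lo = max(flank, half)
    hi = len(genome) - max(flank, half)
    index: dict[str, list[int]] = {}
    gseq = genome.upper()
    for pos in range(lo, hi):
        ctx = gseq[pos - half : pos + half + 1]
        if any(b not in "ACGT" for b in ctx):
            continue
        index.setdefault(ctx, []).append(pos)
    return ContextIndex(
        k=k, flank=flank,
        positions={c: np.asarray(p, dtype=np.int64) for c, p in index.items()},
    )


def _context_of(genome: str, pos: int, k: int) -> str:
    half = k // 2
    return genome[pos - half : pos + half + 1].upper()


def context_matched_null(
    genome: str,
    observed_sites: Sequence[int],
    table: DinucleotidePropertyTable,
    prop: str = "curvature",
    k: int = 3,
    flank: int = 50,
    n_perm: int = 1000,
    seed: int | None = None,
    index: ContextIndex | None = None,
    universe: np.ndarray | None = None,
    check_contexts: bool = False,
) -> PermutationResult:
    """Context-matched permutation null for the mean site-centred curvature.

    ``observed_sites`` are 0-based genome positions. The statistic is the
    mean (2*flank+1)-bp ``prop`` value over the observed sites. Each null
    replicate draws, independently for every observed site (with
    replacement across sites), one uniform random pseudo-site with the
    identical centred k-mer context from the rest of the genome (all
    observed positions excluded); the p-value is lower-tail. Recurrent
    observed positions each draw their own pseudo-site.

    ``universe`` optionally restricts pseudo-site sampling to a subset of
    positions (used by :func:`region_restricted_null`).
    """
    observed_sites = np.asarray(observed_sites, dtype=np.int64)
    if len(observed_sites) == 0:
        raise ValueError("no observed sites")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if index is None:
        index = build_context_index(genome, k=k, flank=flank)
    curv = site_profile(genome, prop, table, flank=flank)
    obs_vals = curv[observed_sites]
    if not np.all(np.isfinite(obs_vals)):
        bad = observed_sites[~np.isfinite(obs_vals)]
        raise ValueError(f"observed sites not scoreable (incomplete flank): {bad.tolist()}")
    observed = float(obs_vals.mean())

    observed_set = set(observed_sites.tolist())
    universe_set = None if universe is None else set(np.asarray(universe).tolist())
    # per observed site: the pool of alternative same-context positions
    pools: list[np.ndarray] = []
    missing = []
    for pos in observed_sites:
        ctx = _context_of(genome, int(pos), k)
        cand = index.positions.get(ctx, np.empty(0, dtype=np.int64))
        allowed = [c for c in cand.tolist() if c not in observed_set
                   and (universe_set is None or c in universe_set)]
        if not allowed:
            missing.append(ctx)
        pools.append(np.asarray(allowed, dtype=np.int64))
    if missing:
        raise ValueError(
            "contexts with no alternative positions: " + ", ".join(sorted(set(missing)))
        )

    rng = np.random.default_rng(seed)
    draws = np.empty((len(pools), n_perm), dtype=np.int64)
    for i, pool in enumerate(pools):
        draws[i] = pool[rng.integers(0, len(pool), size=n_perm)]
    if check_contexts:
        for i, pos in enumerate(observed_sites):
            ctx = _context_of(genome, int(pos), k)
            for q in draws[i]:
                assert _context_of(genome, int(q), k) == ctx
    null_means = curv[draws].mean(axis=0)
    p_raw, p = empirical_p(observed, null_means, "lower")
    return PermutationResult(
        observed=observed,
        null=null_means,
        tail="lower",
        p_raw=p_raw,
        p=p,
        seed=seed,
        n_perm=n_perm,
        statistic=f"mean {2 * flank + 1}-bp {prop} at observed sites",
    )


def read_bed_classes(path) -> pd.DataFrame:
    """BED with the region class in the name column -> DataFrame
    (start, end, region_class); 0-based half-open, single contig assumed."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("BED annotation needs 4 columns (contig start end class)")
    return pd.DataFrame(
        {"start": df[1].astype(int), "end": df[2].astype(int), "region_class": df[3]}
    )


def region_restricted_null(
    genome: str,
    annotation: pd.DataFrame,
    snv_positions: Sequence[int],
    region_class: str,
    table: DinucleotidePropertyTable,
    prop: str = "curvature",
    context_match: bool = True,
    k: int = 3,
    flank: int = 50,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[PermutationResult, int]:
    """Context-matched null with the sampling universe restricted to one
    annotated region class.

    ``annotation`` has columns (start, end, region_class), 0-based half-open
    and disjoint. SNVs outside the class are excluded; the count of excluded
    sites is returned alongside the result. With ``context_match=False`` the
    matching is relaxed to k=1, i.e. pseudo-sites only share the mutated
    base itself, mirroring analyses that sample class positions freely.
    """
    ann = annotation[annotation["region_class"] == region_class]
    if ann.empty:
        raise ValueError(f"no annotation rows with class {region_class!r}")
    in_class = np.zeros(len(genome), dtype=bool)
    for _, row in ann.iterrows():
        in_class[int(row.start) : int(row.end)] = True
    snv_positions = np.asarray(snv_positions, dtype=np.int64)
    keep = in_class[snv_positions]
    excluded = int((~keep).sum())
    kept = snv_positions[keep]
    if len(kept) == 0:
        raise ValueError(f"no SNVs fall in region class {region_class!r}")
    k_eff = k if context_match else 1
    universe = np.flatnonzero(in_class)
    result = context_matched_null(
        genome,
        kept,
        table,
        prop=prop,
        k=k_eff,
        flank=flank,
        n_perm=n_perm,
        seed=seed,
        universe=universe,
    )
    return result, excluded
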