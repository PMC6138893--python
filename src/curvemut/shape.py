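"""Dinucleotide-model DNA shape features.

Intrinsic DNA curvature and the other structural/thermodynamic properties
are scored as frequency-weighted linear features: a sequence region is
summarised by the frequencies of its 16 overlapping dinucleotides, and a
property value is the dot product of those frequencies with a per-property
16-vector of parameters (a :class:`DinucleotidePropertyTable` row).

The module provides single-region scoring (:func:`property_value`),
sliding-window profiles (:func:`window_profile`), and site-centred flank
scoring for mutation sites (:func:`flanking_value`, :func:`site_profile`).
Coordinates are 0-based half-open internally; user-facing tables are
1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DINUCLEOTIDES",
    "DinucleotidePropertyTable",
    "WindowGrid",
    "FeatureTrack",
    "UnscoreableSiteError",
    "load_default_table",
    "dinucleotide_counts",
    "dinucleotide_frequencies",
    "property_value",
    "gc_content",
    "window_profile",
    "flanking_value",
    "site_profile",
    "reverse_complement",
]

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: fraction of skipped (ambiguous) dinucleotides above which a window is flagged
AMBIGUITY_FLAG_FRACTION = 0.10


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class UnscoreableSiteError(ValueError):
    """Raised when a site's flanking window overruns its contig."""


@dataclass(frozen=True)
class DinucleotidePropertyTable:
    """Per-dinucleotide parameters for a set of named DNA properties.

    ``values`` maps each property name to a 16-vector ordered like
    :data:`DINUCLEOTIDES` (AA, AC, ..., TT). ``provenance`` is free text
    describing the source of the parameters.
    """

    values: Mapping[str, np.ndarray]
    provenance: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for prop, vec in self.values.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (16,):
                raise ValueError(
                    f"property {prop!r} must have exactly 16 values, got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"property {prop!r} contains non-finite values")
            clean[prop] = arr
        object.__setattr__(self, "values", clean)

    @property
    def property_names(self) -> list[str]:
        return list(self.values)

    def vector(self, prop: str) -> np.ndarray:
        try:
            return self.values[prop]
        except KeyError:
            raise KeyError(
                f"unknown property {prop!r}; available: {', '.join(self.values)}"
            ) from None

    def __contains__(self, prop: str) -> bool:
        return prop in self.values

    @classmethod
    def uniform(cls, value: float = 1.0, properties: Iterable[str] = ("uniform",)):
        """Table assigning the same value to all 16 dinucleotides (testing aid)."""
        return cls(
            {p: np.full(16, float(value)) for p in properties},
            provenance=f"uniform table, v={value}",
        )

    def symmetrized(self) -> "DinucleotidePropertyTable":
        """Average each value with its reverse-complement dinucleotide's value."""
        rc_idx = np.array(
            [DINUCLEOTIDES.index(reverse_complement(d)) for d in DINUCLEOTIDES]
        )
        return DinucleotidePropertyTable(
            {p: (v + v[rc_idx]) / 2.0 for p, v in self.values.items()},
            provenance=self.provenance + " [strand-symmetrized]",
        )

    @classmethod
    def from_tsv(cls, path) -> "DinucleotidePropertyTable":
        """Read a table: comment lines ``#`` (kept as provenance), then a
        header ``property`` + the 16 dinucleotides AA..TT, one row per property."""
        provenance_lines = []
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                provenance_lines.append(line[1:].strip())
            elif line.strip():
                body.append(line)
        header = body[0].rstrip("\n").split("\t")
        if header[0] != "property" or tuple(header[1:]) != DINUCLEOTIDES:
            raise ValueError(
                "property table header must be 'property' followed by the 16 "
                "dinucleotides AA..TT in lexicographic order"
            )
        values = {}
        for line in body[1:]:
            fields = line.rstrip("\n").split("\t")
            values[fields[0]] = np.array([float(x) for x in fields[1:]])
        return cls(values, provenance="\n".join(provenance_lines))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for line in self.provenance.splitlines():
                fh.write(f"# {line}\n")
            fh.write("property\t" + "\t".join(DINUCLEOTIDES) + "\n")
            for prop, vec in self.values.items():
                fh.write(prop + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {d: [self.values[p][i] for p in self.values] for i, d in enumerate(DINUCLEOTIDES)},
            index=list(self.values),
        )


def load_default_table() -> DinucleotidePropertyTable:
    """The packaged 17-property table (curvature, tilt, roll, twist, ...)."""
    ref = resources.files("curvemut.data") / "dinucleotide_properties.tsv"
    with resources.as_file(ref) as path:
        return DinucleotidePropertyTable.from_tsv(path)


def _encode(seq: str) -> np.ndarray:
    """Base codes A,C,G,T -> 0..3; anything else -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _dinuc_codes(seq: str) -> np.ndarray:
    """Per-position dinucleotide code (0..15) for positions 0..len-2; -1 if
    either base is ambiguous."""
    codes = _encode(seq)
    a, b = codes[:-1], codes[1:]
    d = 4 * a + b
    d[(a < 0) | (b < 0)] = -1
    return d


def dinucleotide_counts(seq: str, ambiguous: str = "skip") -> tuple[np.ndarray, int]:
    """Counts of the 16 overlapping dinucleotides; returns (counts, n_skipped).

    ``ambiguous='skip'`` drops dinucleotides containing non-ACGT bases and
    reduces the denominator; ``'error'`` raises on any ambiguous base.
    """
    if len(seq) < 2:
        raise ValueError(f"sequence of length {len(seq)} has no dinucleotides")
    d = _dinuc_codes(seq)
    skipped = int((d < 0).sum())
    if skipped and ambiguous == "error":
        raise ValueError(f"sequence contains {skipped} ambiguous dinucleotides")
    counts = np.bincount(d[d >= 0], minlength=16).astype(float)
    return counts, skipped


def dinucleotide_frequencies(seq: str, ambiguous: str = "skip") -> np.ndarray:
    """Frequencies of the 16 overlapping dinucleotides (sum to 1)."""
    counts, _ = dinucleotide_counts(seq, ambiguous=ambiguous)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous dinucleotides in sequence")
    return counts / total


def property_value(
    seq: str,
    prop: str,
    table: DinucleotidePropertyTable,
    strand_agnostic: bool = False,
    ambiguous: str = "skip",
) -> float:
    """Frequency-weighted linear property score of a region.

    Returns sum_d f_d * v(prop, d) over the 16 dinucleotides d, with f the
    overlapping-dinucleotide frequencies of ``seq``. With
    ``strand_agnostic=True`` the value is averaged with the score of the
    reverse complement.
    """
    vec = table.vector(prop)
    value = float(dinucleotide_frequencies(seq, ambiguous=ambiguous) @ vec)
    if strand_agnostic:
        rc = float(dinucleotide_frequencies(reverse_complement(seq), ambiguous=ambiguous) @ vec)
        value = (value + rc) / 2.0
    return value


def gc_content(seq: str) -> float:
    """Fraction of G+C over sequence length (non-ACGT bases count toward length)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window coordinates: length ``L``, slide ``step`` over ``seq_len``."""

    L: int
    step: int
    seq_len: int

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("window length must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def n_windows(self) -> int:
        if self.seq_len < self.L:
            return 0
        return (self.seq_len - self.L) // self.step + 1

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.step

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.L


@dataclass
class FeatureTrack:
    """Per-window values of one property on a :class:`WindowGrid`."""

    grid: WindowGrid
    values: np.ndarray
    property_name: str
    flags: np.ndarray = field(default=None)  # e.g. high-ambiguity windows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_windows:
            raise ValueError("track length does not match window grid")
        if self.flags is None:
            self.flags = np.zeros(len(self.values), dtype=bool)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_index": np.arange(len(self.values)),
                "start": self.grid.starts,
                "end": self.grid.ends,
                "value": self.values,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_bedgraph(self, path, contig: str) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            for _, row in df.iterrows():
                fh.write(f"{contig}\t{int(row.start)}\t{int(row.end)}\t{row.value:.10g}\n")


def window_profile(
    seq: str,
    L: int,
    step: int,
    prop: str,
    table: DinucleotidePropertyTable,
) -> FeatureTrack:
    """Property profile over sliding windows of length ``L`` sliding by ``step``."""
    vec = table.vector(prop)
    grid = WindowGrid(L=L, step=step, seq_len=len(seq))
    if grid.n_windows == 0:
        warnings.warn(
            f"window length {L} exceeds sequence length {len(seq)}: empty track",
            stacklevel=2,
        )
        return FeatureTrack(grid, np.empty(0), prop)

    d = _dinuc_codes(seq)
    valid = d >= 0
    per_pos = np.where(valid, vec[np.clip(d, 0, 15)], 0.0)
    # cumulative sums give O(1) window sums
    cs_val = np.concatenate([[0.0], np.cumsum(per_pos)])
    cs_n = np.concatenate([[0], np.cumsum(valid.astype(int))])
    starts = grid.starts
    ends = starts + (L - 1)  # number of dinucleotides per window = L-1
    sums = cs_val[ends] - cs_val[starts]
    ns = cs_n[ends] - cs_n[starts]
    with np.errstate(invalid="ignore"):
        values = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    flags = (L - 1 - ns) > AMBIGUITY_FLAG_FRACTION * (L - 1)
    return FeatureTrack(grid, values, prop, flags=flags)


def site_profile(
    seq: str,
    prop: str,
    table: DinucleotidePropertyTable,
    flank: int = 50,
) -> np.ndarray:
    """Site-centred flank score for every position of ``seq``.

    Entry ``i`` is the property value of the (2*flank+1)-bp window centred on
    position ``i``; positions whose window overruns the sequence are NaN.
    """
    L = 2 * flank + 1
    track = window_profile(seq, L=L, step=1, prop=prop, table=table)
    out = np.full(len(seq), np.nan)
    if len(track) > 0:
        out[flank : flank + len(track)] = track.values
    return out


def flanking_value(
    seqs: Mapping[str, str] | str,
    site: tuple[str, int] | int,
    prop: str,
    table: DinucleotidePropertyTable,
    flank: int = 50,
) -> float:
    """Property value over the (2*flank+1)-bp region centred on a site.

    ``seqs`` may be a single sequence (with ``site`` a 0-based position) or a
    mapping contig -> sequence (with ``site`` a (contig, position) pair).
    Raises :class:`UnscoreableSiteError` when the window overruns the contig.
    """
    if isinstance(seqs, str):
        contig_name, pos = "<seq>", int(site)
        seq = seqs
    else:
        contig_name, pos = site
        seq = seqs[contig_name]
    start, end = pos - flank, pos + flank + 1
    if start < 0 or end > len(seq):
        raise UnscoreableSiteError(
            f"site {contig_name}:{pos} flank window [{start}, {end}) overruns "
            f"contig of length {len(seq)}"
        )
    return property_value(seq[start:end], prop, table)
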