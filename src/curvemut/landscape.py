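"""Mutational landscape of a coding sequence from selected loss-of-function mutants.

Builds the per-site landscape of potential nonsense mutation sites (positions
where a single-base substitution creates a stop codon), counts how many
independent samples/plates observed each, derives windowed mutation rates, and
relates the rate to DNA shape features through Spearman/partial correlations
and an AIC ladder of ordinary least-squares models.

Positions in user-facing tables are 1-based inclusive; internally 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

from .shape import DinucleotidePropertyTable, FeatureTrack, WindowGrid, site_profile

__all__ = [
    "STOP_CODONS",
    "CodingSequence",
    "MutationRecord",
    "MutationSet",
    "NonsenseSite",
    "SiteLandscape",
    "CorrelationResult",
    "ModelComparison",
    "load_ura3_cds",
    "is_transition",
    "enumerate_potential_nonsense_sites",
    "classify_mutation",
    "per_site_counts",
    "per_nucleotide_rates",
    "window_mutation_rate",
    "correlate_features",
    "partial_spearman",
    "fit_site_models",
    "logistic_snv_model",
    "binned_type_rates",
    "gene_set_compare",
    "normalize_snv_type",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
_PYRIMIDINE_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def is_transition(ref: str, alt: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine substitution."""
    return (ref.upper(), alt.upper()) in _TRANSITIONS


@dataclass(frozen=True)
class CodingSequence:
    """A coding sequence, 5'->3' on the coding strand.

    Length must be divisible by 3 with no internal in-frame stop codon; a
    terminal stop codon is allowed (and excluded from nonsense-site
    enumeration).
    """

    id: str
    sequence: str
    anchor: tuple[str, int, str] | None = None  # (contig, 0-based start, strand)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS {self.id!r} length {len(seq)} not divisible by 3")
        codons = self.codons
        for i, codon in enumerate(codons[:-1]):
            if codon in STOP_CODONS:
                raise ValueError(
                    f"CDS {self.id!r} has internal in-frame stop {codon} at codon {i + 1}"
                )

    @property
    def codons(self) -> list[str]:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]

    @property
    def has_terminal_stop(self) -> bool:
        return self.sequence[-3:] in STOP_CODONS

    @property
    def protein(self) -> str:
        return str(Seq(self.sequence).translate())

    @classmethod
    def from_fasta(cls, path, id: str | None = None) -> "CodingSequence":
        for rec in SeqIO.parse(str(path), "fasta"):
            if id is None or rec.id == id:
                return cls(rec.id, str(rec.seq))
        raise ValueError(f"no record {id!r} in {path}")


def load_ura3_cds() -> CodingSequence:
    """The packaged wild-type S288C URA3 coding sequence (804 bp)."""
    ref = resources.files("curvemut.data") / "ura3_cds.fasta"
    with resources.as_file(ref) as path:
        return CodingSequence.from_fasta(path)


@dataclass(frozen=True)
class MutationRecord:
    """One observed variant: sample/plate id, 1-based position, ref and alt base."""

    sample_id: str
    position: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at position {self.position}")

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.position, self.ref, self.alt)


@dataclass
class MutationSet:
    """A collection of mutation records plus deduplication semantics.

    Identical mutations (same position, ref and alt) observed in the same
    sample/plate are counted once after :meth:`deduplicate` — recurrences
    within a plate are overwhelmingly clonal expansions of a single event.
    """

    records: list[MutationRecord]
    deduplicated: bool = False
    n_duplicates_removed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def deduplicate(self) -> "MutationSet":
        seen = set()
        kept = []
        for rec in self.records:
            if rec.key not in seen:
                seen.add(rec.key)
                kept.append(rec)
        return MutationSet(
            kept, deduplicated=True, n_duplicates_removed=len(self.records) - len(kept)
        )

    def validate_against(self, cds: CodingSequence) -> None:
        """Hard error when any record's ref base mismatches the sequence."""
        for rec in self.records:
            if not 1 <= rec.position <= len(cds.sequence):
                raise ValueError(f"position {rec.position} outside CDS {cds.id!r}")
            actual = cds.sequence[rec.position - 1]
            if actual != rec.ref:
                raise ValueError(
                    f"ref mismatch at position {rec.position}: record says "
                    f"{rec.ref}, sequence has {actual}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.position, r.ref, r.alt) for r in self.records],
            columns=["sample_id", "position", "ref", "alt"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MutationSet":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        required = {"sample_id", "position", "ref", "alt"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        recs = [
            MutationRecord(str(r.sample_id), int(r.position), str(r.ref), str(r.alt))
            for r in df.itertuples()
        ]
        return cls(recs)

    @classmethod
    def from_vcf(cls, path, sample_column: str = "SAMPLE") -> "MutationSet":
        """Read SNVs from a (plain-text) VCF; sample id taken from an INFO key
        or, failing that, the CHROM field."""
        recs = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                chrom, pos, _, ref, alts = fields[0], int(fields[1]), *fields[2:5]
                info = fields[7] if len(fields) > 7 else ""
                sample = chrom
                for kv in info.split(";"):
                    if kv.startswith(sample_column + "="):
                        sample = kv.split("=", 1)[1]
                for alt in alts.split(","):
                    if len(ref) == 1 and len(alt) == 1 and alt in "ACGT":
                        recs.append(MutationRecord(sample, pos, ref, alt))
        return cls(recs)


@dataclass(frozen=True)
class NonsenseSite:
    """A potential nonsense site: a position where >=1 substitution creates a stop."""

    position: int  # 1-based CDS coordinate
    ref: str
    substitutions: tuple[str, ...]  # alt bases creating TAA/TAG/TGA

    @property
    def transition_alts(self) -> tuple[str, ...]:
        return tuple(a for a in self.substitutions if is_transition(self.ref, a))


@dataclass
class SiteLandscape:
    """Per potential-nonsense-site observation counts over a CDS."""

    cds: CodingSequence
    sites: list[NonsenseSite]
    counts: np.ndarray = None
    n_unmapped: int = 0  # nonsense records not at an enumerated site

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros(len(self.sites), dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.sites):
            raise ValueError("counts length does not match number of sites")

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [s.position for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "stop_creating_alts": [",".join(s.substitutions) for s in self.sites],
                "count": self.counts,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def enumerate_potential_nonsense_sites(cds: CodingSequence) -> SiteLandscape:
    """All positions where a single-base substitution yields TAA/TAG/TGA.

    The terminal stop codon (when present) is excluded. A position is one
    site even when several substitutions there create stops; the full
    substitution set is retained per site.
    """
    seq = cds.sequence
    codons = cds.codons
    last = len(codons) - 1 if cds.has_terminal_stop else len(codons)
    sites = []
    for ci in range(last):
        codon = codons[ci]
        for off in range(3):
            pos0 = 3 * ci + off
            ref = seq[pos0]
            alts = tuple(
                alt
                for alt in "ACGT"
                if alt != ref and codon[:off] + alt + codon[off + 1 :] in STOP_CODONS
            )
            if alts:
                sites.append(NonsenseSite(position=pos0 + 1, ref=ref, substitutions=alts))
    return SiteLandscape(cds=cds, sites=sites)


def classify_mutation(cds: CodingSequence, record: MutationRecord) -> str:
    """Classify a CDS point mutation as synonymous, missense or nonsense."""
    pos0 = record.position - 1
    if not 0 <= pos0 < len(cds.sequence):
        raise ValueError(f"position {record.position} outside CDS {cds.id!r}")
    if cds.sequence[pos0] != record.ref:
        raise ValueError(
            f"ref mismatch at position {record.position}: record says {record.ref}, "
            f"sequence has {cds.sequence[pos0]}"
        )
    ci, off = divmod(pos0, 3)
    codon = cds.codons[ci]
    mutant = codon[:off] + record.alt + codon[off + 1 :]
    if mutant in STOP_CODONS:
        return "nonsense"
    aa_before = str(Seq(codon).translate())
    aa_after = str(Seq(mutant).translate())
    return "synonymous" if aa_before == aa_after else "missense"


def per_site_counts(skeleton: SiteLandscape, mutations: MutationSet) -> SiteLandscape:
    """Fill a landscape: per-site count = number of distinct samples/plates
    with a stop-creating substitution at that site.

    Input records are deduplicated first if needed. Nonsense records whose
    (position, alt) is not among the enumerated stop-creating substitutions
    are tallied in ``n_unmapped``.
    """
    if not mutations.deduplicated:
        mutations = mutations.deduplicate()
    mutations.validate_against(skeleton.cds)
    sub_to_site = {}
    for i, s in enumerate(skeleton.sites):
        for alt in s.substitutions:
            sub_to_site[(s.position, alt)] = i
    samples_per_site: list[set] = [set() for _ in skeleton.sites]
    unmapped = 0
    for rec in mutations:
        if classify_mutation(skeleton.cds, rec) != "nonsense":
            continue
        idx = sub_to_site.get((rec.position, rec.alt))
        if idx is None:
            unmapped += 1
        else:
            samples_per_site[idx].add(rec.sample_id)
    counts = np.array([len(s) for s in samples_per_site], dtype=int)
    return SiteLandscape(
        cds=skeleton.cds, sites=skeleton.sites, counts=counts, n_unmapped=unmapped
    )


def per_nucleotide_rates(landscape: SiteLandscape) -> dict[str, float]:
    """Mean per-site count per reference base; bases with no potential site -> NaN."""
    rates = {}
    refs = np.array([s.ref for s in landscape.sites])
    for base in "ACGT":
        mask = refs == base
        if mask.sum() == 0:
            rates[base] = float("nan")
            warnings.warn(f"no potential nonsense sites with reference base {base}")
        else:
            rates[base] = float(landscape.counts[mask].mean())
    return rates


def window_mutation_rate(landscape: SiteLandscape, L: int, step: int) -> FeatureTrack:
    """Per-window mutation rate: total observed counts / number of potential
    sites in the window. Windows without potential sites get NaN and are
    flagged (exclude them before correlating)."""
    seq_len = len(landscape.cds.sequence)
    grid = WindowGrid(L=L, step=step, seq_len=seq_len)
    pos0 = landscape.positions - 1
    values = np.full(grid.n_windows, np.nan)
    flags = np.zeros(grid.n_windows, dtype=bool)
    for w, start in enumerate(grid.starts):
        in_win = (pos0 >= start) & (pos0 < start + L)
        n_sites = int(in_win.sum())
        if n_sites == 0:
            flags[w] = True
        else:
            values[w] = landscape.counts[in_win].sum() / n_sites
    return FeatureTrack(grid, values, "mutation_rate", flags=flags)


@dataclass(frozen=True)
class CorrelationResult:
    property_name: str
    rho: float
    p_value: float
    n: int
    control: str | None = None
    flagged: bool = False
    note: str = ""


def correlate_features(
    rate_track: FeatureTrack, feature_tracks: Sequence[FeatureTrack]
) -> list[CorrelationResult]:
    """Spearman correlation of the rate track with each feature track, ranked
    by |rho|. Tracks must share the rate track's grid; windows with NaN in
    either variable are dropped pairwise."""
    results = []
    for ft in feature_tracks:
        if ft.grid != rate_track.grid:
            raise ValueError(f"grid mismatch for feature {ft.property_name!r}")
        ok = np.isfinite(rate_track.values) & np.isfinite(ft.values)
        x, y = rate_track.values[ok], ft.values[ok]
        n = int(ok.sum())
        if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
            results.append(
                CorrelationResult(ft.property_name, float("nan"), float("nan"), n,
                                  flagged=True, note="constant or too few pairs")
            )
            continue
        rho, p = stats.spearmanr(x, y)
        results.append(CorrelationResult(ft.property_name, float(rho), float(p), n))
    results.sort(key=lambda r: -abs(r.rho) if np.isfinite(r.rho) else 1.0)
    return results


def partial_spearman(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, labels=("x", "y", "control")
) -> CorrelationResult:
    """First-order partial Spearman correlation of x and y controlling z.

    Variables are rank-transformed, then
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    The p-value uses the t approximation on n-3 degrees of freedom.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete observations")

    def _corr(a, b):
        if np.all(a == a[0]) or np.all(b == b[0]):
            return 0.0  # a constant variable carries no rank information
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        return float(np.corrcoef(ra, rb)[0, 1])

    r_xy, r_xz, r_yz = _corr(x, y), _corr(x, z), _corr(y, z)
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        return CorrelationResult(
            labels[1], float("nan"), float("nan"), n, control=labels[2],
            flagged=True, note="control collinear with a variable",
        )
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(labels[1], r, p, n, control=labels[2])


@dataclass
class ModelComparison:
    label: str
    formula: str
    aic: float
    adj_r2: float
    coefficients: pd.DataFrame
    n: int
    k: int  # number of regression parameters (excluding error variance)
    dropped_terms: tuple[str, ...] = ()


#: the standard model ladder: base identity at the site and its neighbours,
#: and the curvature of the site-centred 101-bp region
DEFAULT_SITE_MODELS = (
    ("1", "null", ()),
    ("2", "base0", ("b0",)),
    ("3", "base0+neighbours1", ("b0", "bp1", "bm1")),
    ("4", "base0+neighbours3", ("b0", "bp1", "bp2", "bp3", "bm1", "bm2", "bm3")),
    ("5", "curvature", ("curvature",)),
    ("6", "base0+curvature", ("b0", "curvature")),
)


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC = n ln(RSS/n) + n ln(2 pi) + n + 2(k+1); k+1 counts the error
    variance so the convention is uniform across models. RSS is floored at a
    tiny positive value so a perfectly fitted (e.g. constant) response keeps
    AIC finite and the parameter penalty still orders nested models."""
    return n * np.log(max(rss, 1e-12) / n) + n * np.log(2 * np.pi) + n + 2 * (k + 1)


def site_model_frame(
    landscape: SiteLandscape, curvature_at_sites: np.ndarray
) -> pd.DataFrame:
    """One row per potential nonsense site: count, base identity at offsets
    -3..+3 relative to the site, and the supplied site-centred curvature.
    Sites lacking a complete offset context or a finite curvature are dropped
    so all models are fitted on identical observations."""
    seq = landscape.cds.sequence
    curvature_at_sites = np.asarray(curvature_at_sites, dtype=float)
    if len(curvature_at_sites) != len(landscape.sites):
        raise ValueError("curvature_at_sites length must match number of sites")
    rows = []
    for i, s in enumerate(landscape.sites):
        pos0 = s.position - 1
        if pos0 - 3 < 0 or pos0 + 3 >= len(seq) or not np.isfinite(curvature_at_sites[i]):
            continue
        rows.append(
            {
                "position": s.position,
                "count": landscape.counts[i],
                "b0": seq[pos0],
                "bp1": seq[pos0 + 1],
                "bp2": seq[pos0 + 2],
                "bp3": seq[pos0 + 3],
                "bm1": seq[pos0 - 1],
                "bm2": seq[pos0 - 2],
                "bm3": seq[pos0 - 3],
                "curvature": curvature_at_sites[i],
            }
        )
    return pd.DataFrame(rows)


def _design_matrix(df: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list, list]:
    """Intercept + one-hot (drop-first) categoricals + numeric curvature;
    zero-variance columns are dropped with a warning."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    dropped = []
    for term in terms:
        if term == "curvature":
            col = df["curvature"].to_numpy(dtype=float)
            if np.ptp(col) == 0:
                dropped.append(term)
                continue
            cols.append(col)
            names.append("curvature")
        else:
            levels = sorted(df[term].unique())
            for lev in levels[1:]:
                col = (df[term] == lev).to_numpy(dtype=float)
                if np.ptp(col) == 0:
                    dropped.append(f"{term}[{lev}]")
                    continue
                cols.append(col)
                names.append(f"{term}[{lev}]")
            if len(levels) == 1:
                dropped.append(term)
    if dropped:
        warnings.warn(f"dropped zero-variance predictors: {dropped}")
    return np.column_stack(cols), names, dropped


def fit_site_models(
    landscape: SiteLandscape,
    curvature_at_sites: np.ndarray,
    models: Sequence[tuple] = DEFAULT_SITE_MODELS,
) -> list[ModelComparison]:
    """Fit the per-site OLS model ladder and report AIC and adjusted r^2.

    Response is the per-site observation count; all models are fitted on the
    same rows (sites with complete -3..+3 context and finite curvature).
    """
    import statsmodels.api as sm

    df = site_model_frame(landscape, curvature_at_sites)
    results = []
    for label, name, terms in models:
        X, names, dropped = _design_matrix(df, terms)
        if X.shape[0] <= X.shape[1]:
            raise ValueError(
                f"model {label} ({name}): {X.shape[0]} observations for "
                f"{X.shape[1]} parameters"
            )
        fit = sm.OLS(df["count"].to_numpy(dtype=float), X).fit()
        rss = float(fit.ssr)
        k = X.shape[1]
        coef = pd.DataFrame(
            {"term": names, "estimate": fit.params, "se": fit.bse, "p": fit.pvalues}
        )
        results.append(
            ModelComparison(
                label=label,
                formula=name,
                aic=float(_gaussian_aic(rss, len(df), k)),
                adj_r2=float(fit.rsquared_adj),
                coefficients=coef,
                n=len(df),
                k=k,
                dropped_terms=tuple(dropped),
            )
        )
    return results


def model_comparison_frame(results: Sequence[ModelComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.label for r in results],
            "formula": [r.formula for r in results],
            "AIC": [r.aic for r in results],
            "adj_r2": [r.adj_r2 for r in results],
            "n": [r.n for r in results],
        }
    )


def logistic_snv_model(site_table: pd.DataFrame) -> pd.DataFrame:
    """Logistic regression of per-site mutated/not on base identities and
    curvature.

    ``site_table`` needs a binary ``mutated`` column plus the predictor
    columns of :func:`site_model_frame` (b0, bp1..bm3 categorical,
    curvature numeric). Returns a coefficient table with a ``separable``
    flag when a coefficient diverges (perfect separation).
    """
    import statsmodels.api as sm

    terms = [c for c in ("b0", "bp1", "bp2", "bp3", "bm1", "bm2", "bm3", "curvature")
             if c in site_table.columns]
    X, names, _ = _design_matrix(site_table, terms)
    y = site_table["mutated"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            params, bse = fit.params, fit.bse
        except Exception:
            converged = False
            fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
            params = np.asarray(fit.params)
            bse = np.full_like(params, np.nan)
    out = pd.DataFrame({"term": names, "estimate": params, "se": bse})
    out["z"] = out["estimate"] / out["se"]
    out["separable"] = (not converged) | (np.abs(out["estimate"]) > 15)
    return out


def normalize_snv_type(ref: str, alt: str) -> str:
    """Pyrimidine-normalized substitution type: purine-reference SNVs are
    complemented so every type has a C or T reference."""
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{ref}>{alt}"


def binned_type_rates(
    genome: str,
    snvs: MutationSet,
    n_samples: int,
    table: DinucleotidePropertyTable,
    n_bins: int = 10,
    flank: int = 50,
    prop: str = "curvature",
) -> pd.DataFrame:
    """Per-curvature-bin, per-substitution-type mutation rates.

    All scoreable genome positions are ranked by site-centred curvature and
    cut into ``n_bins`` equal-size bins. For each pyrimidine-normalized type
    the rate in a bin is #SNVs / (n_samples x #at-risk positions), at-risk
    meaning positions whose reference base (or its complement) matches the
    type's reference pyrimidine.
    """
    curv = site_profile(genome, prop, table, flank=flank)
    scoreable = np.flatnonzero(np.isfinite(curv))
    if len(scoreable) < n_bins:
        raise ValueError("fewer scoreable positions than bins")
    order = scoreable[np.argsort(curv[scoreable], kind="stable")]
    bins = np.array_split(order, n_bins)  # sizes differ by at most 1
    bin_of = np.full(len(genome), -1, dtype=int)
    for b, positions in enumerate(bins):
        bin_of[positions] = b

    snvs = snvs.deduplicate() if not snvs.deduplicated else snvs
    gseq = genome.upper()
    rows = []
    for b, positions in enumerate(bins):
        bases = np.frombuffer(gseq.encode(), dtype=np.uint8)[positions]
        n_cg = int(((bases == ord("C")) | (bases == ord("G"))).sum())
        n_at = int(((bases == ord("A")) | (bases == ord("T"))).sum())
        at_risk = {"C": n_cg, "T": n_at}
        tallies = {t: 0 for t in _PYRIMIDINE_TYPES}
        for rec in snvs:
            pos0 = rec.position - 1
            if 0 <= pos0 < len(genome) and bin_of[pos0] == b:
                tallies[normalize_snv_type(rec.ref, rec.alt)] += 1
        for t in _PYRIMIDINE_TYPES:
            denom = n_samples * at_risk[t[0]]
            rows.append(
                {
                    "bin": b,
                    "type": t,
                    "n_snvs": tallies[t],
                    "at_risk_positions": at_risk[t[0]],
                    "rate": tallies[t] / denom if denom else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def gene_set_compare(
    curvatures_a: Sequence[float],
    curvatures_b: Sequence[float],
    alternative: str = "greater",
) -> float:
    """One-tailed Mann-Whitney U p-value comparing per-gene mean curvatures
    (alternative: set A greater/less than set B)."""
    from .fluctuation import compare_samples

    return compare_samples(curvatures_a, curvatures_b, alternative=alternative)
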