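"""Synthetic inputs with the statistical structure the analyses assume.

Generators for every input class the pipeline consumes: random genomes with
controllable dinucleotide composition, genome-wide mutation sites whose rate
depends (negatively) on local intrinsic curvature, selection-style
nonsense-mutant tables over a CDS, overdispersed fluctuation-assay colony
counts, and a full synthetic analogue of a Sanger-sequenced loss-of-function
mutant table with its published marginal structure.

The curvature -> rate link is exponential, lambda_i = lambda0 * exp(-beta *
z_i), with z_i the standardized site-centred (101-bp) curvature: positivity
is guaranteed and the effect is a rate ratio per curvature unit, matching
how such effects are reported (a fixed relative drop in curvature multiplies
the rate by a fixed factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fluctuation import FluctuationDataset
from .landscape import (
    CodingSequence,
    MutationRecord,
    MutationSet,
    SiteLandscape,
    enumerate_potential_nonsense_sites,
    is_transition,
)
from .shape import DINUCLEOTIDES, DinucleotidePropertyTable, site_profile

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "effect_size_from_rate_ratio",
    "simulate_site_mutations",
    "simulate_cds_landscape",
    "simulate_fluctuation",
    "simulate_selection_table",
]

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Bundle of generator settings (used by the CLI ``simulate`` command)."""

    genome_length: int = 100000
    composition: Sequence[float] | None = None  # 16 target dinucleotide freqs
    beta: float = 1.0  # curvature effect per standardized curvature unit
    lambda0: float = 0.01  # baseline per-site per-sample mutation rate
    n_samples: int = 50
    seed: int | None = None
    burst_dispersion: float = 1.0  # mean mutant-clone size for plating sims

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if self.genome_length < 101:
            raise ValueError("genome length must be >= 101 (one full flank window)")


def simulate_genome(
    length: int,
    composition: Sequence[float] | None = None,
    seed: int | None = None,
) -> str:
    """Random DNA sequence, optionally with target dinucleotide composition.

    With ``composition`` (16 non-negative weights in AA..TT order) the
    sequence is drawn from the first-order Markov chain whose transition
    probabilities are proportional to the target dinucleotide frequencies,
    so realized frequencies approach the target as length grows.
    """
    rng = np.random.default_rng(seed)
    if length < 1:
        raise ValueError("length must be >= 1")
    if composition is None:
        return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (16,) or (comp < 0).any() or comp.sum() == 0:
        raise ValueError("composition must be 16 non-negative weights (AA..TT)")
    comp = comp / comp.sum()
    freq = comp.reshape(4, 4)  # freq[i, j] = f(base_i base_j)
    marginal = freq.sum(axis=1)
    trans = np.zeros((4, 4))
    for i in range(4):
        if marginal[i] > 0:
            trans[i] = freq[i] / marginal[i]
        else:
            trans[i] = 0.25  # unreachable state; arbitrary
    start = rng.choice(4, p=marginal / marginal.sum())
    out = np.empty(length, dtype=np.int64)
    out[0] = start
    # cumulative transition rows let us vectorize the chain per segment
    cum = trans.cumsum(axis=1)
    u = rng.random(length - 1)
    cur = start
    for t in range(1, length):
        cur = int(np.searchsorted(cum[cur], u[t - 1], side="right"))
        cur = min(cur, 3)
        out[t] = cur
    return "".join(_BASES[i] for i in out)


def effect_size_from_rate_ratio(
    curvature_values: np.ndarray,
    relative_decrease: float = 0.10,
    rate_ratio: float = 1.70,
) -> float:
    """Convert a reported ratio-type effect into beta per standardized unit.

    If a ``relative_decrease`` (e.g. 10%) in curvature multiplies the rate by
    ``rate_ratio`` (e.g. 1.7), the exponential link gives a slope of
    ln(rate_ratio)/relative_decrease per unit of *relative* curvature; one
    standardized unit of the supplied curvature values corresponds to
    sd/mean relative units, hence
    beta = ln(rate_ratio)/relative_decrease * sd/|mean|.
    """
    vals = np.asarray(curvature_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    mean, sd = vals.mean(), vals.std(ddof=1)
    if mean == 0:
        raise ValueError("mean curvature is 0; relative effect undefined")
    return float(np.log(rate_ratio) / relative_decrease * sd / abs(mean))


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def simulate_site_mutations(
    genome: str,
    table: DinucleotidePropertyTable,
    beta: float,
    lambda0: float,
    n_samples: int,
    seed: int | None = None,
    flank: int = 50,
    prop: str = "curvature",
    return_rates: bool = False,
):
    """Genome-wide mutation sites with curvature-dependent rates.

    Every scoreable position i gets rate lambda_i = lambda0*exp(-beta*z_i)
    with z_i its standardized site-centred curvature; each of ``n_samples``
    samples mutates site i independently with probability 1 - exp(-lambda_i).
    Alt bases are uniform over the three non-reference bases.
    """
    if lambda0 <= 0:
        raise ValueError("lambda0 must be > 0")
    rng = np.random.default_rng(seed)
    curv = site_profile(genome, prop, table, flank=flank)
    scoreable = np.flatnonzero(np.isfinite(curv))
    z = _standardize(curv[scoreable])
    lam = lambda0 * np.exp(-beta * z)
    p = 1.0 - np.exp(-lam)
    gseq = genome.upper()
    records = []
    for s in range(n_samples):
        hits = scoreable[rng.random(len(scoreable)) < p]
        for pos in hits:
            ref = gseq[pos]
            alts = [b for b in _BASES if b != ref]
            alt = alts[rng.integers(0, 3)]
            records.append(MutationRecord(f"sample{s + 1}", int(pos) + 1, ref, alt))
    mutations = MutationSet(records, deduplicated=True)
    if return_rates:
        return mutations, scoreable, lam
    return mutations


def _site_curvature_for_cds(
    cds: CodingSequence,
    landscape: SiteLandscape,
    table: DinucleotidePropertyTable,
    prop: str = "curvature",
    flank: int = 50,
) -> np.ndarray:
    """Site-centred curvature for each potential nonsense site, clipping the
    window at the CDS boundaries (no genomic flanks are assumed)."""
    seq = cds.sequence
    vals = np.empty(len(landscape.sites))
    from .shape import property_value

    for i, s in enumerate(landscape.sites):
        pos0 = s.position - 1
        start = max(0, pos0 - flank)
        end = min(len(seq), pos0 + flank + 1)
        vals[i] = property_value(seq[start:end], prop, table)
    return vals


def simulate_cds_landscape(
    cds: CodingSequence,
    table: DinucleotidePropertyTable,
    beta: float,
    lambda0: float,
    n_plates: int,
    seed: int | None = None,
    prop: str = "curvature",
    flank: int = 50,
) -> MutationSet:
    """Selection-style nonsense mutant table over a CDS.

    Only mutations at potential nonsense sites are emitted (the selection
    analogue: other mutations do not survive the screen). Per plate and per
    stop-creating substitution, an event occurs with probability
    1 - exp(-lambda_i) where lambda_i = lambda0*exp(-beta*z_i) and z_i is
    the standardized site curvature; a plate reports at most one record per
    (site, substitution), matching the post-deduplication semantics.
    """
    if lambda0 < 0:
        raise ValueError("lambda0 must be >= 0")
    rng = np.random.default_rng(seed)
    skeleton = enumerate_potential_nonsense_sites(cds)
    curv = _site_curvature_for_cds(cds, skeleton, table, prop=prop, flank=flank)
    z = _standardize(curv)
    lam = lambda0 * np.exp(-beta * z)
    p_site = 1.0 - np.exp(-lam)
    records = []
    for plate in range(n_plates):
        plate_id = f"plate{plate + 1}"
        for i, s in enumerate(skeleton.sites):
            if rng.random() < p_site[i]:
                alt = s.substitutions[rng.integers(0, len(s.substitutions))]
                records.append(MutationRecord(plate_id, s.position, s.ref, alt))
    return MutationSet(records, deduplicated=True)


def simulate_fluctuation(
    m_true: float,
    n_plates: int,
    burst_dispersion: float = 1.0,
    seed: int | None = None,
    strain: str = "sim",
) -> FluctuationDataset:
    """Overdispersed colony counts with an exact p0 target.

    Mutational events per plate are Poisson(m_true); each event founds a
    clone whose colony count is geometric (support >= 1) with mean
    ``burst_dispersion``. P(zero colonies) = e^{-m_true} exactly for any
    burst size, so the p0 estimator's target is analytic, while
    burst_dispersion > 1 makes the counts overdispersed (VMR > 1) like real
    jackpot-prone fluctuation data.
    """
    if m_true < 0:
        raise ValueError("m_true must be >= 0")
    if burst_dispersion < 1:
        raise ValueError("burst_dispersion is a mean clone size, must be >= 1")
    rng = np.random.default_rng(seed)
    events = rng.poisson(m_true, size=n_plates)
    counts = np.zeros(n_plates, dtype=int)
    total_events = int(events.sum())
    if total_events:
        bursts = rng.geometric(1.0 / burst_dispersion, size=total_events)
        counts = np.add.reduceat(
            np.concatenate([bursts, [0]]),
            np.concatenate([[0], np.cumsum(events)[:-1]]),
        )
        counts[events == 0] = 0
    return FluctuationDataset(strain, counts.astype(int))


def simulate_selection_table(
    cds: CodingSequence,
    table: DinucleotidePropertyTable,
    n_plates: int = 135,
    beta: float | None = None,
    seed: int | None = None,
    n_nonsense_transitions: int = 54,
    n_nonsense_transversions: int = 100,
    n_missense: int = 293,
    n_synonymous: int = 5,
    max_site_plates: int = 8,
    n_rows_total: int = 1000,
    transition_rate_ratio: float | None = None,
    prop: str = "curvature",
    flank: int = 50,
    max_tries: int = 2000,
) -> MutationSet:
    """Synthetic analogue of a Sanger-sequenced loss-of-function mutant table.

    Emulates the published summary structure of such a selection experiment:
    a fixed number of deduplicated nonsense records split into transitions
    and transversions, plus missense and synonymous passengers, spread over
    ``n_plates`` plates, with the per-site plate count capped at (and
    reaching) ``max_site_plates`` and clonal within-plate duplicate rows
    padding the table to roughly ``n_rows_total`` sequenced isolates.

    Site usage is biased by curvature (rate multiplier exp(-beta*z), with
    beta defaulting to the rate-ratio calibration of
    :func:`effect_size_from_rate_ratio`) and by substitution class
    (transitions are per-substitution hotter than transversions;
    ``transition_rate_ratio`` defaults to the ratio implied by the target
    transition/transversion record counts and the CDS's available
    substitution types). Draws are conditioned so that the realized per-site
    maximum equals ``max_site_plates``.
    """
    rng = np.random.default_rng(seed)
    skeleton = enumerate_potential_nonsense_sites(cds)
    curv = _site_curvature_for_cds(cds, skeleton, table, prop=prop, flank=flank)
    z = _standardize(curv)
    if beta is None:
        beta = effect_size_from_rate_ratio(curv)
    site_w = np.exp(-beta * z)

    # stop-creating substitutions grouped by class
    ti_subs, tv_subs = [], []  # (site_index, alt)
    for i, s in enumerate(skeleton.sites):
        for alt in s.substitutions:
            (ti_subs if is_transition(s.ref, alt) else tv_subs).append((i, alt))
    if transition_rate_ratio is None:
        # per-substitution ratio implied by the target record tallies
        transition_rate_ratio = (n_nonsense_transitions / max(len(ti_subs), 1)) / (
            n_nonsense_transversions / max(len(tv_subs), 1)
        )

    def _draw_class(subs, n_events, counts):
        """Sample n_events substitution events, site counts capped at
        max_site_plates; returns list of (site_index, alt) or None if stuck."""
        idx = np.arange(len(subs))
        w = np.array([site_w[i] for i, _ in subs], dtype=float)
        chosen = []
        for _ in range(n_events):
            mask = np.array(
                [counts[i] < max_site_plates for i, _ in subs], dtype=float
            )
            ww = w * mask
            tot = ww.sum()
            if tot == 0:
                return None
            j = int(rng.choice(idx, p=ww / tot))
            site_i, alt = subs[j]
            counts[site_i] += 1
            chosen.append((site_i, alt))
        return chosen

    for attempt in range(max_tries):
        counts = np.zeros(len(skeleton.sites), dtype=int)
        ti_events = _draw_class(ti_subs, n_nonsense_transitions, counts)
        if ti_events is None:
            continue
        tv_events = _draw_class(tv_subs, n_nonsense_transversions, counts)
        if tv_events is None:
            continue
        if counts.max() == max_site_plates:
            break
    else:
        raise RuntimeError(
            f"could not realize a per-site maximum of {max_site_plates} in "
            f"{max_tries} attempts; adjust beta or the targets"
        )

    # assign distinct plates per site so the per-site plate count equals the
    # per-site event count
    records = []
    events_by_site: dict[int, list[str]] = {}
    for site_i, alt in ti_events + tv_events:
        events_by_site.setdefault(site_i, []).append(alt)
    for site_i, alts in events_by_site.items():
        s = skeleton.sites[site_i]
        plates = rng.choice(n_plates, size=len(alts), replace=False)
        for alt, plate in zip(alts, plates):
            records.append(MutationRecord(f"plate{plate + 1}", s.position, s.ref, alt))

    # missense / synonymous passengers: sample distinct (plate, pos, ref, alt)
    from .landscape import classify_mutation

    seq = cds.sequence
    pos_curv = np.empty(len(seq))
    from .shape import property_value as _pv

    for pos0 in range(len(seq)):
        start = max(0, pos0 - flank)
        end = min(len(seq), pos0 + flank + 1)
        pos_curv[pos0] = _pv(seq[start:end], prop, table)
    zpos = _standardize(pos_curv)
    wpos = np.exp(-beta * zpos)

    candidates = {"missense": [], "synonymous": []}
    weights = {"missense": [], "synonymous": []}
    for pos0 in range(len(seq)):
        ref = seq[pos0]
        for alt in _BASES:
            if alt == ref:
                continue
            rec = MutationRecord("probe", pos0 + 1, ref, alt)
            cls = classify_mutation(cds, rec)
            if cls in candidates:
                w = wpos[pos0] * (transition_rate_ratio if is_transition(ref, alt) else 1.0)
                candidates[cls].append((pos0 + 1, ref, alt))
                weights[cls].append(w)

    for cls, n_target in (("missense", n_missense), ("synonymous", n_synonymous)):
        cand, w = candidates[cls], np.asarray(weights[cls], dtype=float)
        if n_target > len(cand) * n_plates:
            raise ValueError(f"cannot place {n_target} distinct {cls} records")
        w = w / w.sum()
        seen = set()
        while len(seen) < n_target:
            j = int(rng.choice(len(cand), p=w))
            plate = int(rng.integers(0, n_plates))
            key = (plate, *cand[j])
            if key in seen:
                continue
            seen.add(key)
            pos, ref, alt = cand[j]
            records.append(MutationRecord(f"plate{plate + 1}", pos, ref, alt))

    # clonal duplicates: repeat existing rows (same plate, same mutation) so
    # the raw table resembles the sequenced-isolate count before dedup
    n_dup = max(0, n_rows_total - len(records))
    base = list(records)
    for _ in range(n_dup):
        records.append(base[int(rng.integers(0, len(base)))])
    rng.shuffle(records)  # type: ignore[arg-type]
    return MutationSet(records, deduplicated=False)
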