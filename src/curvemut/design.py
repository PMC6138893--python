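"""Constrained synonymous recoding to raise or lower intrinsic DNA curvature.

Designs synonymous variants of a coding sequence whose dinucleotide-model
curvature is increased or decreased while GC content, codon adaptation index
(CAI) and local mRNA secondary-structure strength stay within tolerances of
the wild type. The search is simulated annealing over single-codon
synonymous swaps: simple, seedable, and checkable against exhaustive
enumeration on small inputs.

Structure strength is the mean minimum free energy (MFE) over all 20-nt
windows of the CDS; the folding engine is an injected callable seq -> energy
(a zero stub ships for tests, a ViennaRNA-backed engine is available when
the RNA bindings or the RNAfold binary are installed).
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .landscape import CodingSequence
from .shape import DinucleotidePropertyTable, gc_content, property_value

__all__ = [
    "DesignConstraints",
    "DesignResult",
    "cai",
    "read_cai_weights",
    "cai_weights_from_reference",
    "structure_strength",
    "zero_engine",
    "gc_engine",
    "rnafold_engine",
    "synonymous_codons",
    "enumerate_synonymous_variants",
    "design_synonymous_variant",
]

_STOPS = set(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)

# amino acid -> tuple of codons
_AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in _CODON_TO_AA.items():
    _AA_TO_CODONS.setdefault(aa, ())
    _AA_TO_CODONS[aa] += (codon,)


def synonymous_codons(codon: str) -> tuple[str, ...]:
    """All codons encoding the same amino acid (including the input); stop
    codons only map to themselves."""
    codon = codon.upper()
    if codon in _STOPS:
        return (codon,)
    return _AA_TO_CODONS[_CODON_TO_AA[codon]]


def cai(cds: CodingSequence | str, weights: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of relative-adaptiveness
    weights over the coding codons (stop codon excluded).

    Weights must be positive; by convention the optimal codon of each amino
    acid has weight 1.
    """
    seq = cds.sequence if isinstance(cds, CodingSequence) else cds.upper()
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    log_sum, n = 0.0, 0
    for codon in codons:
        if codon in _STOPS:
            continue
        w = weights.get(codon)
        if w is None:
            raise KeyError(f"no CAI weight for codon {codon}")
        if w <= 0:
            raise ValueError(f"CAI weight for {codon} must be positive, got {w}")
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise ValueError("no coding codons")
    return math.exp(log_sum / n)


def read_cai_weights(path) -> dict[str, float]:
    """Read a ``codon  w`` TSV of relative-adaptiveness weights."""
    df = pd.read_csv(path, sep="\t")
    if not {"codon", "w"}.issubset(df.columns):
        raise ValueError("weights table needs columns 'codon' and 'w'")
    return {str(r.codon).upper(): float(r.w) for r in df.itertuples()}


def cai_weights_from_reference(sequences: Iterable[str]) -> dict[str, float]:
    """Relative-adaptiveness weights from a reference gene set.

    Counts codon usage over the reference CDSs and sets
    w(codon) = count(codon) / max count among its synonyms (zero counts get
    a small pseudo-weight so CAI stays defined).
    """
    counts: dict[str, int] = {c: 0 for c in _CODON_TO_AA}
    for seq in sequences:
        seq = seq.upper()
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    weights = {}
    for aa, codons in _AA_TO_CODONS.items():
        top = max(counts[c] for c in codons)
        for c in codons:
            weights[c] = counts[c] / top if top > 0 else 1.0
            if weights[c] == 0:
                weights[c] = 0.5 / max(top, 1)
    return weights


def zero_engine(seq: str) -> float:
    """Stub folding engine: every window has zero free energy."""
    return 0.0


def gc_engine(seq: str) -> float:
    """Toy engine: energy = -(number of G or C bases); oracle-checkable."""
    s = seq.upper()
    return -(s.count("G") + s.count("C"))


def rnafold_engine() -> Callable[[str], float]:
    """A ViennaRNA-backed MFE engine (python bindings if importable, else the
    RNAfold binary). Raises ImportError when neither is available."""
    try:
        import RNA  # type: ignore

        def engine(seq: str) -> float:
            _, mfe = RNA.fold(seq.replace("T", "U"))
            return float(mfe)

        return engine
    except ImportError:
        pass
    if shutil.which("RNAfold"):

        def engine(seq: str) -> float:
            out = subprocess.run(
                ["RNAfold", "--noPS"],
                input=seq.replace("T", "U") + "\n",
                capture_output=True,
                text=True,
                check=True,
            ).stdout
            last = out.strip().splitlines()[-1]
            return float(last[last.rindex("(") + 1 : last.rindex(")")])

        return engine
    raise ImportError("no ViennaRNA python bindings and no RNAfold binary on PATH")


def structure_strength(
    cds: CodingSequence | str,
    folding_engine: Callable[[str], float] = zero_engine,
    window: int = 20,
) -> float:
    """Mean MFE over all ``window``-nt windows of the CDS (len - window + 1
    windows, slide 1); the average local structure strength of the transcript."""
    seq = cds.sequence if isinstance(cds, CodingSequence) else cds.upper()
    if len(seq) < window:
        raise ValueError(f"sequence shorter than the {window}-nt folding window")
    energies = [folding_engine(seq[i : i + window]) for i in range(len(seq) - window + 1)]
    return float(np.mean(energies))


@dataclass
class DesignConstraints:
    """Tolerances around the wild-type values ("largely unchanged") and the
    objective direction.

    ``gc_tol`` is an absolute GC fraction, ``cai_tol`` absolute CAI units,
    ``structure_tol_frac`` a fraction of the wild-type structure strength.
    """

    direction: str  # "increase" | "decrease"
    gc_tol: float = 0.01
    cai_tol: float = 0.05
    structure_tol_frac: float = 0.05
    max_iterations: int = 20000
    seed: int | None = 0
    initial_temperature: float = 1.0
    cooling: float = 0.9995

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")
        for name in ("gc_tol", "cai_tol", "structure_tol_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DesignResult:
    sequence: str
    objective: float  # curvature of the emitted variant
    wt_metrics: dict
    variant_metrics: dict
    iterations: int
    converged: bool
    note: str = ""
    best_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "objective_curvature": self.objective,
            "wild_type": self.wt_metrics,
            "variant": self.variant_metrics,
            "iterations": self.iterations,
            "converged": self.converged,
            "note": self.note,
        }


def _metrics(seq, table, prop, weights, engine) -> dict:
    if engine is zero_engine:  # stub: every window scores 0, skip the scan
        strength = 0.0
    else:
        strength = structure_strength(seq, engine)
    return {
        "curvature": property_value(seq, prop, table),
        "gc": gc_content(seq),
        "cai": cai(seq, weights),
        "structure_strength": strength,
    }


def _violation(m: dict, wt: dict, c: DesignConstraints) -> float:
    """Total constraint violation (0 when feasible)."""
    v = max(0.0, abs(m["gc"] - wt["gc"]) - c.gc_tol)
    v += max(0.0, abs(m["cai"] - wt["cai"]) - c.cai_tol)
    struct_tol = abs(wt["structure_strength"]) * c.structure_tol_frac
    v += max(0.0, abs(m["structure_strength"] - wt["structure_strength"]) - struct_tol)
    return v


def enumerate_synonymous_variants(cds: CodingSequence, limit: int = 100000):
    """Yield every synonymous variant sequence (exhaustive; guard on size)."""
    options = [synonymous_codons(c) for c in cds.codons]
    total = 1
    for opt in options:
        total *= len(opt)
        if total > limit:
            raise ValueError(f"variant space exceeds limit of {limit}")
    for combo in product(*options):
        yield "".join(combo)


def design_synonymous_variant(
    cds: CodingSequence,
    constraints: DesignConstraints,
    table: DinucleotidePropertyTable,
    cai_weights: Mapping[str, float] | None = None,
    folding_engine: Callable[[str], float] = zero_engine,
    prop: str = "curvature",
) -> DesignResult:
    """Search for a synonymous variant with in/decreased curvature under the
    GC / CAI / structure-strength constraints.

    Simulated annealing with geometric cooling over single-codon synonymous
    swaps; a candidate's score is the signed curvature minus a large penalty
    per unit of constraint violation, and the best *feasible* sequence seen
    is returned. Non-convergence (no feasible improvement found) yields a
    diagnostic result, not an exception.
    """
    if cai_weights is None:
        # neutral weights: CAI == 1 for every sequence, constraint inactive
        cai_weights = {c: 1.0 for c in _CODON_TO_AA}
    if folding_engine is not zero_engine:
        # windows recur across annealing proposals; memoize engine calls
        folding_engine = lru_cache(maxsize=200000)(folding_engine)
    wt = _metrics(cds.sequence, table, prop, cai_weights, folding_engine)
    sign = 1.0 if constraints.direction == "increase" else -1.0

    degenerate = [i for i, c in enumerate(cds.codons) if len(synonymous_codons(c)) > 1]
    if not degenerate:
        return DesignResult(
            sequence=cds.sequence,
            objective=wt["curvature"],
            wt_metrics=wt,
            variant_metrics=dict(wt),
            iterations=0,
            converged=True,
            note="no degenerate codons; input returned unchanged",
        )

    rng = np.random.default_rng(constraints.seed)
    penalty = 1e4

    def score(m: dict) -> float:
        return sign * m["curvature"] - penalty * _violation(m, wt, constraints)

    codons = list(cds.codons)
    current = "".join(codons)
    cur_m = dict(wt)
    cur_score = score(cur_m)
    best_seq, best_m = current, dict(wt)
    best_obj = sign * wt["curvature"]
    improved = False
    temperature = constraints.initial_temperature
    trace = [best_obj]

    for it in range(1, constraints.max_iterations + 1):
        ci = degenerate[rng.integers(0, len(degenerate))]
        alts = [c for c in synonymous_codons(codons[ci]) if c != codons[ci]]
        new_codon = alts[rng.integers(0, len(alts))]
        cand_codons = codons.copy()
        cand_codons[ci] = new_codon
        cand = "".join(cand_codons)
        cand_m = _metrics(cand, table, prop, cai_weights, folding_engine)
        cand_score = score(cand_m)
        delta = cand_score - cur_score
        if delta >= 0 or rng.random() < math.exp(delta / max(temperature, 1e-12)):
            codons, current, cur_m, cur_score = cand_codons, cand, cand_m, cand_score
            if _violation(cur_m, wt, constraints) == 0 and sign * cur_m["curvature"] > best_obj:
                best_seq, best_m = current, dict(cur_m)
                best_obj = sign * cur_m["curvature"]
                improved = True
                trace.append(best_obj)
        temperature *= constraints.cooling

    variant = CodingSequence(cds.id + "_variant", best_seq)  # validates the ORF
    assert str(Seq(best_seq).translate()) == cds.protein, "protein changed during design"
    converged = improved and _violation(best_m, wt, constraints) == 0
    note = "" if converged else (
        "no feasible variant improved the objective within max_iterations"
    )
    return DesignResult(
        sequence=variant.sequence,
        objective=best_m["curvature"],
        wt_metrics=wt,
        variant_metrics=best_m,
        iterations=constraints.max_iterations,
        converged=converged,
        note=note,
        best_trace=trace,
    )
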