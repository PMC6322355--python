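"""Ensemble aggregation and multitarget prioritization indices.

The pipeline turns raw per-structure docking scores into a compound
ranking for multitarget insecticide discovery:

1. **Ensemble aggregation** — a compound's score for a target, ``MD_i``,
   is the arithmetic mean of its scores over the available receptor
   structures of that target (ensemble docking against, e.g., two PDB
   entries per enzyme).
2. **Reference selection** — per target, the reference score ``MD_r`` is
   the most negative ``MD_i`` over all compounds (the ligand with the best
   predicted affinity); ties break to the lexicographically smallest
   compound id.
3. **Virtual multitarget index** — ``vMTi = sum_t MD_i(t) / MD_r(t)``
   over the designated index targets (here the three insect targets EcR,
   PPO and DmAChE). Each ratio lies in (0, 1] when all scores are
   negative, so vMTi is bounded by the number of index targets and is
   invariant to rescaling any one target's scores.
4. **Weighed multitarget index** — ``wMTi = sum_t n_t * MD_i(t)/MD_r(t)``
   over all weighted targets, with a desirability coefficient ``n_t`` per
   target. The shipped defaults give +0.3 to the insect targets and -0.3
   to the human off-target hAChE, penalizing predicted human toxicity.
5. **Selectivity ratio** — ``SR = MD_i(insect) / MD_i(human)``; values
   above 1 indicate predicted preference for the insect enzyme.

Internal arithmetic is full double precision; the reporting layer rounds
half-away-from-zero to two decimals, the convention of the published
tables this implementation reproduces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    MissingScoreError,
    NonNegativeScoreError,
    ReferenceSelectionError,
)
from .score_model import ScoreTable

DEFAULT_COEFFICIENTS: dict[str, float] = {
    "EcR": 0.3,
    "PPO": 0.3,
    "DmAChE": 0.3,
    "hAChE": -0.3,
}
DEFAULT_INDEX_TARGETS: tuple[str, ...] = ("EcR", "PPO", "DmAChE")


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (so -2.855 -> -2.86, 0.595 -> 0.60)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class AggregatedScores:
    """Per (compound, target) mean docking score MD_i with structure counts."""

    entries: dict[tuple[str, str], float]
    counts: dict[tuple[str, str], int]

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c for c, _ in self.entries))

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(t for _, t in self.entries))

    def get(self, compound_id: str, target_id: str) -> float | None:
        return self.entries.get((compound_id, target_id))

    def score_for(self, compound_id: str, target_id: str) -> float:
        try:
            return self.entries[(compound_id, target_id)]
        except KeyError:
            raise MissingScoreError(
                f"no aggregated score for compound {compound_id!r}, target {target_id!r}"
            ) from None


def aggregate_ensemble(table: ScoreTable) -> AggregatedScores:
    """Average each compound's scores over a target's receptor structures."""
    if len(table) == 0:
        raise ValueError("cannot aggregate an empty score table")
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for r in table.records:
        key = (r.compound_id, r.target_id)
        sums[key] = sums.get(key, 0.0) + r.score
        counts[key] = counts.get(key, 0) + 1
    entries = {key: sums[key] / counts[key] for key in sums}
    return AggregatedScores(entries=entries, counts=counts)


@dataclass(frozen=True)
class Reference:
    """The reference ligand of a target: best (most negative) mean score."""

    compound_id: str
    score: float


class ReferenceMap(dict):
    """target_id -> :class:`Reference` mapping."""


def select_references(
    agg: AggregatedScores, targets: Iterable[str] | None = None
) -> ReferenceMap:
    """Pick, per target, the compound with the minimum mean score MD_r.

    Ties break to the lexicographically smallest compound id. A target
    whose best score is non-negative has no meaningful reference and
    raises :class:`ReferenceSelectionError`.
    """
    targets = tuple(targets) if targets is not None else agg.targets
    refs = ReferenceMap()
    for target in targets:
        candidates = [
            (score, compound)
            for (compound, t), score in agg.entries.items()
            if t == target
        ]
        if not candidates:
            raise ReferenceSelectionError(f"no scores for target {target!r}")
        best_score, best_compound = min(candidates, key=lambda sc: (sc[0], sc[1]))
        if best_score >= 0:
            raise ReferenceSelectionError(
                f"target {target!r} has no negative mean score; "
                f"best is {best_score} ({best_compound})"
            )
        refs[target] = Reference(compound_id=best_compound, score=best_score)
    return refs


@dataclass(frozen=True)
class WeightScheme:
    """Desirability coefficients n per target plus the vMTi target subset."""

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    index_targets: tuple[str, ...] = DEFAULT_INDEX_TARGETS

    @classmethod
    def default(cls) -> "WeightScheme":
        return cls()

    @classmethod
    def from_mapping(cls, data: Mapping) -> "WeightScheme":
        coefficients = {str(k): float(v) for k, v in data["targets"].items()}
        index_targets = tuple(str(t) for t in data["index_targets"])
        return cls(coefficients=coefficients, index_targets=index_targets)

    @classmethod
    def load(cls, path: str | Path) -> "WeightScheme":
        """Load from YAML (JSON being a YAML subset, both work)."""
        with Path(path).open(encoding="utf-8") as handle:
            return cls.from_mapping(yaml.safe_load(handle))

    @property
    def weighted_targets(self) -> tuple[str, ...]:
        return tuple(t for t, n in self.coefficients.items() if n != 0.0)

    def to_mapping(self) -> dict:
        return {
            "targets": dict(self.coefficients),
            "index_targets": list(self.index_targets),
        }


def _affinity_ratio(mdi: float, mdr: float, context: str, strict: bool) -> float:
    """MD_i / MD_r, with non-binders (MD_i >= 0) credited zero affinity."""
    if mdi >= 0:
        if strict:
            raise NonNegativeScoreError(
                f"non-negative mean score {mdi} for {context}"
            )
        warnings.warn(
            f"non-negative mean score {mdi} for {context}; ratio set to 0",
            stacklevel=3,
        )
        return 0.0
    return mdi / mdr


def _summed_index(
    agg: AggregatedScores,
    refs: ReferenceMap,
    terms: Sequence[tuple[str, float]],
    strict: bool,
    impute_missing: bool,
) -> tuple[dict[str, float], list[str]]:
    for target, _ in terms:
        if target not in refs:
            raise ReferenceSelectionError(f"no reference for target {target!r}")
    values: dict[str, float] = {}
    excluded: list[str] = []
    for compound in agg.compounds:
        total = 0.0
        missing = False
        for target, coeff in terms:
            mdi = agg.get(compound, target)
            if mdi is None:
                if impute_missing:
                    continue
                missing = True
                break
            ratio = _affinity_ratio(
                mdi, refs[target].score, f"compound {compound!r}, target {target!r}", strict
            )
            total += coeff * ratio
        if missing:
            if strict:
                raise MissingScoreError(
                    f"compound {compound!r} lacks a score for target {target!r}"
                )
            excluded.append(compound)
        else:
            values[compound] = total
    return values, excluded


def compute_vmti(
    agg: AggregatedScores,
    refs: ReferenceMap,
    scheme: WeightScheme | None = None,
    *,
    strict: bool = False,
    impute_missing: bool = False,
) -> tuple[dict[str, float], list[str]]:
    """vMTi per compound: sum of MD_i/MD_r over the index targets.

    Returns ``(values, excluded)``: compounds missing a required target are
    excluded and listed (default), raise in strict mode, or contribute a
    zero ratio when ``impute_missing`` is set.
    """
    scheme = scheme or WeightScheme.default()
    terms = [(t, 1.0) for t in scheme.index_targets]
    return _summed_index(agg, refs, terms, strict, impute_missing)


def compute_wmti(
    agg: AggregatedScores,
    refs: ReferenceMap,
    scheme: WeightScheme | None = None,
    *,
    strict: bool = False,
    impute_missing: bool = False,
) -> tuple[dict[str, float], list[str]]:
    """wMTi per compound: sum of n_t * MD_i/MD_r over weighted targets."""
    scheme = scheme or WeightScheme.default()
    terms = [(t, scheme.coefficients[t]) for t in scheme.weighted_targets]
    return _summed_index(agg, refs, terms, strict, impute_missing)


def selectivity_ratio(
    agg: AggregatedScores, numerator: str, denominator: str
) -> tuple[dict[str, float], list[str]]:
    """SR per compound: mean score on ``numerator`` over ``denominator``.

    Compounds lacking either score are omitted; a zero denominator leaves
    the ratio undefined and flags the compound (second return value).
    """
    ratios: dict[str, float] = {}
    flagged: list[str] = []
    for compound in agg.compounds:
        num = agg.get(compound, numerator)
        den = agg.get(compound, denominator)
        if num is None or den is None:
            continue
        if den == 0:
            flagged.append(compound)
            continue
        ratios[compound] = num / den
    return ratios, flagged


def rank_descending(values: Mapping[str, float]) -> dict[str, int]:
    """Ordinal 1..n ranks, highest value first; ties in compound-id order."""
    ordered = sorted(values, key=lambda c: (-values[c], c))
    return {compound: rank for rank, compound in enumerate(ordered, start=1)}


@dataclass
class IndexTable:
    """Per-compound index results plus the provenance needed to report them.

    ``rows`` is indexed by compound_id with full-precision columns
    ``vmti``, ``wmti``, one ``ratio_<target>`` per index target, one
    ``sr_<A>_<B>`` per requested selectivity pair, and integer ranks
    ``rank_vmti``/``rank_wmti``.
    """

    rows: pd.DataFrame
    references: ReferenceMap
    scheme: WeightScheme
    excluded: tuple[str, ...] = ()
    sr_flagged: tuple[str, ...] = ()

    def vmti(self, compound_id: str) -> float:
        return float(self.rows.loc[compound_id, "vmti"])

    def wmti(self, compound_id: str) -> float:
        return float(self.rows.loc[compound_id, "wmti"])

    @property
    def sr_columns(self) -> list[str]:
        return [c for c in self.rows.columns if c.startswith("sr_")]

    def to_csv(self, path: str | Path, ndigits: int = 2) -> None:
        """Write the result table, indices rounded for display."""
        out = self.rows.copy()
        for column in ["vmti", "wmti", *self.sr_columns]:
            out[column] = out[column].map(lambda v: round_half_away(v, ndigits))
        columns = ["vmti", "wmti", "rank_vmti", "rank_wmti", *self.sr_columns]
        out[columns].to_csv(path, index_label="compound_id")

    def report(self) -> str:
        """Human-readable account of references and exclusions."""
        lines = ["References (best mean score per target):"]
        for target, ref in self.references.items():
            lines.append(f"  {target}: compound {ref.compound_id} (MDr = {ref.score:g})")
        if self.excluded:
            lines.append("Excluded (missing a required target score): "
                         + ", ".join(self.excluded))
        else:
            lines.append("Excluded: none")
        if self.sr_flagged:
            lines.append("Selectivity undefined (zero denominator): "
                         + ", ".join(self.sr_flagged))
        return "\n".join(lines)


def rank_compounds(index: IndexTable, key: str = "wmti") -> list[str]:
    """Compound ids ordered best-first by ``key`` (vmti, wmti or an sr_* column)."""
    if key not in index.rows.columns:
        raise KeyError(f"unknown ranking key {key!r}")
    values = {c: float(index.rows.loc[c, key]) for c in index.rows.index}
    ranks = rank_descending(values)
    return sorted(ranks, key=ranks.get)


def build_index_table(
    source: ScoreTable | AggregatedScores,
    scheme: WeightScheme | None = None,
    sr_pairs: Sequence[tuple[str, str]] = (("DmAChE", "hAChE"),),
    *,
    strict: bool = False,
    impute_missing: bool = False,
) -> IndexTable:
    """Run the full prioritization: aggregate, reference, index, rank."""
    scheme = scheme or WeightScheme.default()
    agg = aggregate_ensemble(source) if isinstance(source, ScoreTable) else source
    needed = dict.fromkeys((*scheme.index_targets, *scheme.weighted_targets))
    refs = select_references(agg, needed)
    vmti, excluded_v = compute_vmti(
        agg, refs, scheme, strict=strict, impute_missing=impute_missing
    )
    wmti, excluded_w = compute_wmti(
        agg, refs, scheme, strict=strict, impute_missing=impute_missing
    )
    compounds = [c for c in agg.compounds if c in vmti and c in wmti]
    excluded = tuple(dict.fromkeys((*excluded_v, *excluded_w)))
    rows = pd.DataFrame(index=pd.Index(compounds, name="compound_id"))
    rows["vmti"] = [vmti[c] for c in compounds]
    rows["wmti"] = [wmti[c] for c in compounds]
    for target in scheme.index_targets:
        rows[f"ratio_{target}"] = [
            agg.score_for(c, target) / refs[target].score for c in compounds
        ]
    sr_flagged: list[str] = []
    for num, den in sr_pairs:
        ratios, flagged = selectivity_ratio(agg, num, den)
        rows[f"sr_{num}_{den}"] = [ratios.get(c, float("nan")) for c in compounds]
        sr_flagged.extend(flagged)
    vmti_sub = {c: vmti[c] for c in compounds}
    wmti_sub = {c: wmti[c] for c in compounds}
    rank_v = rank_descending(vmti_sub)
    rank_w = rank_descending(wmti_sub)
    rows["rank_vmti"] = [rank_v[c] for c in compounds]
    rows["rank_wmti"] = [rank_w[c] for c in compounds]
    return IndexTable(
        rows=rows,
        references=refs,
        scheme=scheme,
        excluded=excluded,
        sr_flagged=tuple(dict.fromkeys(sr_flagged)),
    )


def write_run_metadata(path: str | Path, config: Mapping) -> None:
    """Serialize a resolved run configuration next to its results."""
    with Path(path).open("w", encoding="utf-8") as handle:
        json.dump(dict(config), handle, indent=2, default=str)
        handle.write("\n")
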