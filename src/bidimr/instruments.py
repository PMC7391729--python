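"""Instrument selection: significance filter, greedy LD pruning, F statistics.

Candidates are ordered by ascending p-value (ties broken by rsid for
determinism) and retained greedily when every known R² against already
retained SNPs is below the pruning threshold.  Pairs absent from the LD
table count as independent by default; a conservative flag treats them as
dependent instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

from .sumstats import LdTable, SnpRecord, SummaryStatsTable

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_MAX = 0.2


def f_statistic(beta: float, se: float) -> float:
    """Single-instrument strength: F = (beta/se)², the squared z-score."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


@dataclass(frozen=True)
class InstrumentSet:
    """LD-pruned, significance-filtered SNPs for one exposure."""

    trait_id: str
    records: tuple[SnpRecord, ...]
    p_threshold: float
    r2_max: float
    f_stats: Mapping[str, float] = field(default_factory=dict)
    label: str = "main"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.f_stats:
            object.__setattr__(
                self,
                "f_stats",
                {rec.rsid: f_statistic(rec.beta, rec.se) for rec in self.records},
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(rec.rsid for rec in self.records)


def select_instruments(
    stats: SummaryStatsTable,
    ld: LdTable | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_R2_MAX,
    unknown_ld_dependent: bool = False,
) -> InstrumentSet:
    """Significance filter (p < ``p_threshold``) plus greedy LD pruning.

    Deterministic: candidates sorted by (pvalue, rsid); a candidate is
    retained iff its R² with every already retained SNP is < ``r2_max``.
    """
    if not (0 < p_threshold < 1):
        raise ValueError(f"p_threshold must be in (0, 1), got {p_threshold}")
    if not (0 < r2_max <= 1):
        raise ValueError(f"r2_max must be in (0, 1], got {r2_max}")
    ld = ld or LdTable()
    unknown_r2 = 1.0 if unknown_ld_dependent else 0.0

    candidates = sorted(
        (rec for rec in stats if rec.pvalue < p_threshold),
        key=lambda rec: (rec.pvalue, rec.rsid),
    )
    retained: list[SnpRecord] = []
    for cand in candidates:
        independent = True
        for kept in retained:
            r2 = ld.get(cand.rsid, kept.rsid)
            if r2 is None:
                r2 = unknown_r2
            if r2 >= r2_max:
                independent = False
                break
        if independent:
            retained.append(cand)
    return InstrumentSet(
        trait_id=stats.trait_id,
        records=tuple(retained),
        p_threshold=p_threshold,
        r2_max=r2_max,
    )


class CrossTraitConflict(NamedTuple):
    rsid_a: str
    trait_a: str
    rsid_b: str
    trait_b: str
    r2: float


def cross_trait_overlap(
    sets: Sequence[InstrumentSet],
    ld: LdTable | None = None,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[CrossTraitConflict]:
    """Cross-set instrument pairs that share an rsid or have known R² ≥ threshold.

    Feeds the sensitivity analysis that excludes variants selected for
    several traits or in LD with another trait's instruments.
    """
    if len(sets) < 2:
        raise ValueError("need at least two instrument sets")
    ld = ld or LdTable()
    conflicts: list[CrossTraitConflict] = []
    for i, set_a in enumerate(sets):
        for set_b in sets[i + 1 :]:
            for rec_a in set_a:
                for rec_b in set_b:
                    if rec_a.rsid == rec_b.rsid:
                        conflicts.append(
                            CrossTraitConflict(
                                rec_a.rsid, set_a.trait_id, rec_b.rsid, set_b.trait_id, 1.0
                            )
                        )
                        continue
                    r2 = ld.get(rec_a.rsid, rec_b.rsid)
                    if r2 is not None and r2 >= r2_max:
                        conflicts.append(
                            CrossTraitConflict(
                                rec_a.rsid, set_a.trait_id, rec_b.rsid, set_b.trait_id, r2
                            )
                        )
    return conflicts


@dataclass(frozen=True)
class SubsetSpec:
    """A post-hoc restriction of an instrument set.

    kind: ``p_max`` (tighten the significance cutoff), ``keep`` (restrict
    to an rsid list, e.g. replicated or annotation-cleared SNPs) or
    ``drop`` (exclude an rsid list, e.g. cross-trait conflicts).
    """

    kind: str
    label: str
    p_max: float | None = None
    rsids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in {"p_max", "keep", "drop"}:
            raise ValueError(f"unknown subset kind {self.kind!r}")
        if self.kind == "p_max" and not (self.p_max and 0 < self.p_max < 1):
            raise ValueError("p_max subset requires p_max in (0, 1)")
        object.__setattr__(self, "rsids", frozenset(self.rsids))


def subset_instruments(instrument_set: InstrumentSet, spec: SubsetSpec) -> InstrumentSet:
    """Apply a :class:`SubsetSpec`, preserving all instrument-set invariants."""
    if spec.kind == "p_max":
        records = tuple(r for r in instrument_set if r.pvalue < spec.p_max)
        p_threshold = min(instrument_set.p_threshold, spec.p_max)
    elif spec.kind == "keep":
        records = tuple(r for r in instrument_set if r.rsid in spec.rsids)
        p_threshold = instrument_set.p_threshold
        if not records and len(instrument_set) > 0:
            warnings.warn(
                f"keep-list for {spec.label!r} is disjoint from instrument set "
                f"{instrument_set.trait_id!r}; resulting set is empty",
                stacklevel=2,
            )
    else:  # drop
        records = tuple(r for r in instrument_set if r.rsid not in spec.rsids)
        p_threshold = instrument_set.p_threshold
    return replace(
        instrument_set,
        records=records,
        p_threshold=p_threshold,
        f_stats={},
        label=spec.label,
    )
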