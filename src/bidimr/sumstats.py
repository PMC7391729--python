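"""Reading, validation and serialization of GWAS summary statistics.

Summary statistics enter as tab-delimited tables (one SNP per row) with a
user-supplied column mapping, because source studies publish heterogeneous
headers.  Linkage-disequilibrium information enters as a long-format table
of pairwise R² values.  Results leave as a fixed-layout TSV with 4
significant digits for estimates and ``6.26E-04``-style p-values.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: canonical SnpRecord field names accepted in column maps
CANONICAL_FIELDS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n",
    "chrom",
    "pos",
)

REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")


class SumstatsError(Exception):
    """Base class for summary-statistics I/O problems."""


class FormatError(SumstatsError):
    """File structure problem: missing column, malformed LD row, ..."""


class ValidationError(SumstatsError):
    """A record violates a domain invariant."""


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One SNP association: effect per copy of ``effect_allele``.

    ``beta``/``se`` are on the trait's native scale (unitless for
    metabolite panels, mL/min/1.73 m² for kidney function).  ``eaf`` and
    ``n`` are optional; operations that need them must say so.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        self._validate()

    def _validate(self) -> None:
        rsid = self.rsid
        if not rsid:
            raise ValidationError("record with empty rsid")
        for name in ("effect_allele", "other_allele"):
            allele = getattr(self, name)
            if allele not in VALID_ALLELES:
                raise ValidationError(
                    f"{rsid}: {name} {allele!r} is not a single nucleotide A/C/G/T"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{rsid}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{rsid}: non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{rsid}: se must be finite and > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{rsid}: pvalue must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{rsid}: eaf must be in (0, 1), got {self.eaf}")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.effect_allele, self.other_allele)


@dataclass(frozen=True)
class SummaryStatsTable:
    """Per-trait collection of :class:`SnpRecord`, unique by rsid."""

    trait_id: str
    source_id: str
    records: tuple[SnpRecord, ...]
    _index: Mapping[str, SnpRecord] = field(
        init=False, repr=False, compare=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        index: dict[str, SnpRecord] = {}
        for rec in self.records:
            if rec.rsid in index:
                raise ValidationError(
                    f"duplicate rsid {rec.rsid} in table {self.trait_id}/{self.source_id}"
                )
            index[rec.rsid] = rec
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, rsid: str) -> SnpRecord | None:
        return self._index.get(rsid)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(rec.rsid for rec in self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(rec) for rec in self.records]
        return pd.DataFrame(rows, columns=list(CANONICAL_FIELDS))


class LdTable:
    """Symmetric lookup of pairwise R² between SNPs.

    An absent pair means "unknown"; callers choose a policy.  ``r2(x, x)``
    is 1 by definition.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None) -> None:
        self._pairs: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise FormatError(f"R² for ({a}, {b}) outside [0, 1]: {r2}")
        if a == b:
            return
        key = self._key(a, b)
        existing = self._pairs.get(key)
        if existing is not None and existing != r2:
            raise FormatError(
                f"conflicting R² for pair ({a}, {b}): {existing} vs {r2}"
            )
        self._pairs[key] = r2

    def get(self, a: str, b: str) -> float | None:
        """Known R² for the pair, 1.0 for identical rsids, None if unknown."""
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b))

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(sorted(self._pairs.items()))

    def __len__(self) -> int:
        return len(self._pairs)


def _coerce_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def records_from_frame(
    frame: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> tuple[list[SnpRecord], list[tuple[int, str]]]:
    """Turn a parsed table into validated records.

    ``column_map`` maps file column names to canonical field names.  Every
    input row becomes either a record or an entry in the rejection list
    ``(row index, reason)``; in strict mode the first problem raises.
    """
    if column_map:
        unknown = set(column_map.values()) - set(CANONICAL_FIELDS)
        if unknown:
            raise FormatError(f"column map targets unknown fields: {sorted(unknown)}")
        missing = set(column_map.keys()) - set(frame.columns)
        if missing:
            raise FormatError(f"mapped columns absent from file: {sorted(missing)}")
        frame = frame.rename(columns=dict(column_map))
    missing_req = [f for f in REQUIRED_FIELDS if f not in frame.columns]
    if missing_req:
        raise FormatError(f"required columns missing: {missing_req}")

    records: list[SnpRecord] = []
    rejections: list[tuple[int, str]] = []
    seen: set[str] = set()
    has = {f: f in frame.columns for f in CANONICAL_FIELDS}
    for i, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))
        try:
            rsid = str(row_d["rsid"])
            if rsid in seen:
                raise ValidationError(f"duplicate rsid {rsid}")
            rec = SnpRecord(
                rsid=rsid,
                effect_allele=str(row_d["effect_allele"]),
                other_allele=str(row_d["other_allele"]),
                beta=float(row_d["beta"]),
                se=float(row_d["se"]),
                pvalue=float(row_d["pvalue"]),
                eaf=_coerce_optional_float(row_d.get("eaf")) if has["eaf"] else None,
                n=_coerce_optional_float(row_d.get("n")) if has["n"] else None,
                chrom=str(row_d["chrom"]) if has["chrom"] and not pd.isna(row_d.get("chrom")) else None,
                pos=int(row_d["pos"]) if has["pos"] and not pd.isna(row_d.get("pos")) else None,
            )
        except (ValidationError, ValueError, TypeError) as exc:
            if strict:
                if isinstance(exc, ValidationError):
                    raise
                raise ValidationError(f"row {i}: {exc}") from exc
            rejections.append((i, str(exc)))
            continue
        seen.add(rec.rsid)
        records.append(rec)
    return records, rejections


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
    source_id: str = "",
    strict: bool = True,
) -> SummaryStatsTable:
    """Read a tab-delimited summary-statistics file into a validated table."""
    frame = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    records, rejections = records_from_frame(frame, column_map, strict=strict)
    if rejections:
        logger.warning(
            "%s: dropped %d of %d rows during lenient parsing",
            path,
            len(rejections),
            len(frame),
        )
    return SummaryStatsTable(trait_id=trait_id, source_id=source_id, records=tuple(records))


def write_sumstats(table: SummaryStatsTable, path) -> None:
    """Write a table back to the tab-delimited dialect ``read_sumstats`` reads."""
    frame = table.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld(path) -> LdTable:
    """Read a long-format LD table (columns rsid_a, rsid_b, r2)."""
    frame = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
    for col in ("rsid_a", "rsid_b", "r2"):
        if col not in frame.columns:
            raise FormatError(f"LD table missing column {col!r}")
    table = LdTable()
    for row in frame.itertuples(index=False):
        table.add(str(row.rsid_a), str(row.rsid_b), float(row.r2))
    return table


def write_ld(table: LdTable, path) -> None:
    rows = [(a, b, r2) for (a, b), r2 in table.items()]
    pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


#: fixed output layout of the results table
RESULT_COLUMNS = (
    "direction",
    "exposure",
    "outcome",
    "source",
    "selection",
    "method",
    "n_snps",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "egger_slope",
    "egger_slope_se",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_p",
    "q",
    "q_p",
    "presso_global_p",
    "significant",
)

_ESTIMATE_COLUMNS = frozenset(
    {
        "estimate",
        "se",
        "ci_low",
        "ci_high",
        "egger_slope",
        "egger_slope_se",
        "egger_intercept",
        "egger_intercept_se",
        "q",
    }
)
_PVALUE_COLUMNS = frozenset({"pvalue", "egger_intercept_p", "q_p", "presso_global_p"})

NA = "NA"


def format_estimate(value: float | None) -> str:
    """Estimates and standard errors to 4 significant digits."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return NA
    return f"{value:.4g}"


def format_pvalue(value: float | None) -> str:
    """Scientific notation with two decimals, e.g. ``6.26E-04``."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return NA
    return f"{value:.2E}"


def write_results(rows: Iterable[Mapping[str, object]], path) -> None:
    """Serialize result rows with deterministic columns and formatting.

    Each row is a mapping from :data:`RESULT_COLUMNS` names to values;
    missing keys and None render as ``NA``.
    """
    lines = ["\t".join(RESULT_COLUMNS)]
    for row in rows:
        cells: list[str] = []
        for col in RESULT_COLUMNS:
            value = row.get(col)
            if value is None:
                cells.append(NA)
            elif col in _ESTIMATE_COLUMNS:
                cells.append(format_estimate(float(value)))
            elif col in _PVALUE_COLUMNS:
                cells.append(format_pvalue(float(value)))
            elif isinstance(value, bool):
                cells.append("yes" if value else "no")
            else:
                cells.append(str(value))
        lines.append("\t".join(cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read back a results TSV (``NA`` becomes NaN/None)."""
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
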