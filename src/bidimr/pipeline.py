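"""Bidirectional analysis orchestration.

Each analysis unit runs select → harmonize → estimate for one
exposure/outcome dataset pair.  The main estimate is the Wald ratio when a
single instrument survives and IVW otherwise; Egger, median, Cochran's Q
and MR-PRESSO attach when enough instruments remain.  Significance is
flagged against a family-wise Bonferroni threshold over the declared
number of forward plus reverse analysis units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import estimators, instruments as ins, sumstats
from .estimators import EggerResult, MREstimate, NotFeasible, PressoResult, QResult
from .harmonize import DEFAULT_EAF_WINDOW, harmonize as _harmonize
from .instruments import SubsetSpec
from .sumstats import LdTable, SummaryStatsTable

DIRECTIONS = ("forward", "reverse")


@dataclass(frozen=True)
class DataRegistry:
    """Loaded summary-statistic tables keyed by id, plus one LD table."""

    tables: Mapping[str, SummaryStatsTable]
    ld: LdTable = field(default_factory=LdTable)


@dataclass(frozen=True)
class AnalysisSpec:
    """One exposure→outcome analysis unit and all its options."""

    analysis_id: str
    direction: str
    exposure_table: str
    outcome_table: str
    p_threshold: float = ins.DEFAULT_P_THRESHOLD
    r2_max: float = ins.DEFAULT_R2_MAX
    unknown_ld_dependent: bool = False
    palindrome_policy: str = "infer_by_eaf"
    eaf_window: float = DEFAULT_EAF_WINDOW
    ivw_mode: str = "fixed"
    presso_nsim: int = 1000
    n_boot: int = 5000
    seed: int = 0
    subsets: tuple[SubsetSpec, ...] = ()
    label: str = "main"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.exposure_table == self.outcome_table:
            raise ValueError(
                "exposure and outcome tables must be distinct (two-sample design)"
            )


@dataclass(frozen=True)
class ResultsRow:
    """One output row in the Table-1-shaped results file."""

    analysis_id: str
    direction: str
    exposure: str
    outcome: str
    source: str
    selection: str
    n_snps: int
    n_selected: int
    n_dropped: int
    main: MREstimate | None = None
    egger: EggerResult | NotFeasible | None = None
    median: MREstimate | NotFeasible | None = None
    q: QResult | None = None
    presso: PressoResult | NotFeasible | None = None
    significant: bool | None = None

    @property
    def analyzable(self) -> bool:
        return self.main is not None

    def to_record(self) -> dict[str, object]:
        rec: dict[str, object] = {
            "direction": self.direction,
            "exposure": self.exposure,
            "outcome": self.outcome,
            "source": self.source,
            "selection": self.selection,
            "method": self.main.method if self.main else None,
            "n_snps": self.n_snps,
            "significant": self.significant,
        }
        if self.main:
            rec.update(
                estimate=self.main.estimate,
                se=self.main.se,
                ci_low=self.main.ci_low,
                ci_high=self.main.ci_high,
                pvalue=self.main.pvalue,
            )
        if isinstance(self.egger, EggerResult):
            rec.update(
                egger_slope=self.egger.slope.estimate,
                egger_slope_se=self.egger.slope.se,
                egger_intercept=self.egger.intercept,
                egger_intercept_se=self.egger.intercept_se,
                egger_intercept_p=self.egger.intercept_pvalue,
            )
        if self.q is not None:
            rec.update(q=self.q.q, q_p=self.q.pvalue)
        if isinstance(self.presso, PressoResult):
            rec["presso_global_p"] = self.presso.global_p
        return rec


def bonferroni_threshold(n_forward: int, n_reverse: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha/(n_forward + n_reverse)."""
    if n_forward < 0 or n_reverse < 0:
        raise ValueError("analysis counts must be non-negative")
    total = n_forward + n_reverse
    if total == 0:
        raise ValueError("at least one analysis required")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / total


def run_analysis(spec: AnalysisSpec, registry: DataRegistry) -> ResultsRow:
    """Execute one analysis unit end to end.

    Zero surviving instruments yields a not-analyzable row, never an
    exception.
    """
    exposure = registry.tables[spec.exposure_table]
    outcome = registry.tables[spec.outcome_table]
    iset = ins.select_instruments(
        exposure,
        registry.ld,
        p_threshold=spec.p_threshold,
        r2_max=spec.r2_max,
        unknown_ld_dependent=spec.unknown_ld_dependent,
    )
    for subset in spec.subsets:
        iset = ins.subset_instruments(iset, subset)
    pairs = _harmonize(
        iset, outcome, policy=spec.palindrome_policy, eaf_window=spec.eaf_window
    )
    usable = [p for p in pairs if p.bx != 0]
    n = len(usable)
    base = dict(
        analysis_id=spec.analysis_id,
        direction=spec.direction,
        exposure=exposure.trait_id,
        outcome=outcome.trait_id,
        source=f"{exposure.source_id}|{outcome.source_id}",
        selection=spec.label,
        n_snps=n,
        n_selected=len(iset),
        n_dropped=pairs.n_dropped,
    )
    if n == 0:
        return ResultsRow(**base)

    if n == 1:
        main = estimators.wald_ratio(usable[0])
    else:
        main = estimators.ivw(usable, mode=spec.ivw_mode)

    egger_res: EggerResult | NotFeasible | None = None
    median_res: MREstimate | NotFeasible | None = None
    q_res: QResult | None = None
    presso_res: PressoResult | NotFeasible | None = None
    if n >= 2:
        q_res = estimators.cochran_q(usable, main)
    if n >= estimators.MIN_PAIRS_SENSITIVITY:
        egger_res = estimators.egger(usable)
        median_res = estimators.median_estimate(
            usable, weighted=True, n_boot=spec.n_boot, seed=spec.seed
        )
        presso_res = estimators.mr_presso(
            usable, n_sim=spec.presso_nsim, seed=spec.seed + 1
        )
    return ResultsRow(main=main, egger=egger_res, median=median_res, q=q_res, presso=presso_res, **base)


def flag_significance(rows: Sequence[ResultsRow], threshold: float) -> list[ResultsRow]:
    """Strict comparison of the main p-value against the family threshold."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    flagged = []
    for row in rows:
        sig = row.main is not None and row.main.pvalue < threshold
        flagged.append(replace(row, significant=sig))
    return flagged


@dataclass(frozen=True)
class SensitivityEntry:
    """One sensitivity re-analysis: LD tightening, p tightening, keep/drop."""

    label: str
    r2_max: float | None = None
    p_max: float | None = None
    keep_rsids: frozenset[str] = frozenset()
    drop_rsids: frozenset[str] = frozenset()

    def apply(self, spec: AnalysisSpec) -> AnalysisSpec:
        subsets = list(spec.subsets)
        kwargs: dict = {"label": self.label}
        if self.r2_max is not None:
            kwargs["r2_max"] = self.r2_max
        if self.p_max is not None:
            subsets.append(SubsetSpec("p_max", label=self.label, p_max=self.p_max))
        if self.keep_rsids:
            subsets.append(SubsetSpec("keep", label=self.label, rsids=self.keep_rsids))
        if self.drop_rsids:
            subsets.append(SubsetSpec("drop", label=self.label, rsids=self.drop_rsids))
        kwargs["subsets"] = tuple(subsets)
        return replace(spec, **kwargs)


def run_sensitivity_suite(
    spec: AnalysisSpec, suite: Sequence[SensitivityEntry], registry: DataRegistry
) -> list[ResultsRow]:
    """One row per suite entry, labelled with its selection id."""
    return [run_analysis(entry.apply(spec), registry) for entry in suite]


# ---------------------------------------------------------------------------
# config-driven execution


def _load_rsid_list(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def load_registry(config: Mapping, base_dir: Path | None = None) -> DataRegistry:
    base = Path(base_dir) if base_dir else Path(".")
    tables: dict[str, SummaryStatsTable] = {}
    for entry in config.get("tables", []):
        tables[entry["id"]] = sumstats.read_sumstats(
            base / entry["path"],
            column_map=entry.get("column_map"),
            trait_id=entry.get("trait", entry["id"]),
            source_id=entry.get("source", ""),
            strict=bool(entry.get("strict", True)),
        )
    ld = sumstats.read_ld(base / config["ld"]) if config.get("ld") else LdTable()
    return DataRegistry(tables=tables, ld=ld)


def _spec_from_entry(entry: Mapping, defaults: Mapping) -> AnalysisSpec:
    merged = {**defaults, **entry}
    return AnalysisSpec(
        analysis_id=merged["analysis_id"],
        direction=merged["direction"],
        exposure_table=merged["exposure_table"],
        outcome_table=merged["outcome_table"],
        p_threshold=float(merged.get("p_threshold", ins.DEFAULT_P_THRESHOLD)),
        r2_max=float(merged.get("r2_max", ins.DEFAULT_R2_MAX)),
        unknown_ld_dependent=bool(merged.get("unknown_ld_dependent", False)),
        palindrome_policy=merged.get("palindrome_policy", "infer_by_eaf"),
        eaf_window=float(merged.get("eaf_window", DEFAULT_EAF_WINDOW)),
        ivw_mode=merged.get("ivw_mode", "fixed"),
        presso_nsim=int(merged.get("presso_nsim", 1000)),
        n_boot=int(merged.get("n_boot", 5000)),
        seed=int(merged.get("seed", 0)),
    )


def _suite_from_config(config: Mapping, base_dir: Path) -> list[SensitivityEntry]:
    suite = []
    for entry in config.get("sensitivity", []):
        keep = (
            _load_rsid_list(base_dir / entry["keep_file"]) if entry.get("keep_file") else frozenset()
        )
        drop = (
            _load_rsid_list(base_dir / entry["drop_file"]) if entry.get("drop_file") else frozenset()
        )
        suite.append(
            SensitivityEntry(
                label=entry["label"],
                r2_max=entry.get("r2_max"),
                p_max=entry.get("p_max"),
                keep_rsids=keep,
                drop_rsids=drop,
            )
        )
    return suite


def run_from_config(config_path, out_dir) -> tuple[list[ResultsRow], dict]:
    """Execute a full YAML-declared bidirectional analysis.

    Writes ``results.tsv`` and ``manifest.json`` to ``out_dir``; pure in
    (config, input files, seed), so repeated runs are byte-identical.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        raw = fh.read()
    config = yaml.safe_load(raw)
    base_dir = config_path.parent
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    registry = load_registry(config, base_dir)
    defaults = {"seed": int(config.get("seed", 0))}
    specs = [_spec_from_entry(entry, defaults) for entry in config.get("analyses", [])]
    suite = _suite_from_config(config, base_dir)

    family = config.get("family") or {}
    n_forward = int(family.get("forward", sum(s.direction == "forward" for s in specs)))
    n_reverse = int(family.get("reverse", sum(s.direction == "reverse" for s in specs)))
    alpha = float(config.get("alpha", 0.05))
    threshold = bonferroni_threshold(n_forward, n_reverse, alpha)

    rows: list[ResultsRow] = []
    for spec in specs:
        rows.append(run_analysis(spec, registry))
        rows.extend(run_sensitivity_suite(spec, suite, registry))
    rows = flag_significance(rows, threshold)

    results_path = out_dir / "results.tsv"
    sumstats.write_results((row.to_record() for row in rows), results_path)

    manifest = {
        "config_sha256": hashlib.sha256(raw.encode()).hexdigest(),
        "seed": defaults["seed"],
        "alpha": alpha,
        "family": {"forward": n_forward, "reverse": n_reverse},
        "threshold": threshold,
        "n_rows": len(rows),
        "analyses": [
            {
                "analysis_id": row.analysis_id,
                "selection": row.selection,
                "n_selected": row.n_selected,
                "n_snps": row.n_snps,
                "n_dropped": row.n_dropped,
                "analyzable": row.analyzable,
            }
            for row in rows
        ],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return rows, manifest


def write_fixture_bundle(registry_tables, ld: LdTable, out_dir, seed: int = 0,
                         analyses: Sequence[Mapping] | None = None,
                         truths: Mapping | None = None) -> Path:
    """Write simulated tables, LD, truth and a ready-to-run config to disk.

    Returns the config path; used by the ``simulate`` CLI subcommand and by
    end-to-end determinism tests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_entries = []
    for key in sorted(registry_tables):
        table = registry_tables[key]
        path = out_dir / f"{key}.tsv"
        sumstats.write_sumstats(table, path)
        table_entries.append(
            {"id": key, "trait": table.trait_id, "source": table.source_id, "path": path.name}
        )
    sumstats.write_ld(ld, out_dir / "ld.tsv")
    if truths:
        truth_json = {k: t.to_dict() for k, t in truths.items()}
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth_json, fh, indent=2, sort_keys=True)
    config = {
        "seed": seed,
        "alpha": 0.05,
        "ld": "ld.tsv",
        "tables": table_entries,
        "analyses": [dict(a) for a in (analyses or [])],
        "sensitivity": [
            {"label": "ld_strict", "r2_max": 0.001},
            {"label": "p_1e-10", "p_max": 1e-10},
            {"label": "p_1e-20", "p_max": 1e-20},
        ],
    }
    config_path = out_dir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
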