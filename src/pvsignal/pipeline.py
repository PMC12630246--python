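"""End-to-end run orchestration: classify -> sample -> build -> estimate -> flag.

A run is fully determined by its manifest (input file hashes + config +
seed); rerunning with the same manifest reproduces every output byte for
byte.  Every filtering step logs counts in/out so mention totals and
missing-data buckets stay auditable.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from pvsignal.contingency import (
    DegenerateComparatorError,
    build_table,
    expand_mentions,
    filter_min_cases,
    load_combination_rules,
)
from pvsignal.icsr import IcsrReport, filter_by_date_window, read_reports
from pvsignal.sampling import sample_noncases
from pvsignal.smq import classify_all, load_smq
from pvsignal.stats import (
    SignalCriteria,
    analyze_table,
    pearson_chi2,
    proportion,
    round_half_up,
    two_sample_t_equal_var,
)

__all__ = ["RunConfig", "RunSummary", "run_analysis", "summarize_cohort"]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "entity",
    "level",
    "comparator",
    "a",
    "b",
    "c",
    "d",
    "corrected",
    "ror",
    "ci_low",
    "ci_high",
    "n_case_mentions",
    "signal",
]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    reports_path: str
    smq_path: str
    output_dir: str
    seed: int
    smq_name: str = "SMQ"
    smq_scope: str = "narrow"
    combinations_path: Optional[str] = None
    ratio: int = 4
    levels: tuple = (2, 5)
    comparator_by_level: dict = field(
        default_factory=lambda: {2: "all_other", 5: "siblings_within_parent"}
    )
    min_cases: int = 5
    z: float = 1.96
    min_ror: float = 2.0
    min_ci_low: float = 1.0
    date_from: Optional[str] = None
    date_to: Optional[str] = None

    def validate(self) -> None:
        for p in (self.reports_path, self.smq_path, self.combinations_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)

    @property
    def criteria(self) -> SignalCriteria:
        return SignalCriteria(
            min_ror=self.min_ror, min_ci_low=self.min_ci_low, min_cases=self.min_cases
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        if "comparator_by_level" in raw:
            raw["comparator_by_level"] = {
                int(k): v for k, v in raw["comparator_by_level"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        return d


@dataclass
class RunSummary:
    """Everything a run produced, in memory."""

    n_reports: int
    n_cases: int
    n_noncases_pool: int
    n_noncases_sampled: int
    case_proportion_pct: float  # of the full pre-sampling database
    descriptives: pd.DataFrame
    results: pd.DataFrame
    signals: list
    skipped_entities: list = field(default_factory=list)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _fmt(x, nd) -> float:
    return round_half_up(float(x), nd)


def summarize_cohort(cases: Sequence[IcsrReport], noncases: Sequence[IcsrReport]) -> pd.DataFrame:
    """Cohort descriptives with per-variable complete-case denominators.

    Sections: sex (chi-square), age (pooled t from complete cases),
    each outcome's 2x2 among outcome-present reports, drugs-per-report
    distribution (2x5 chi-square, bins 1,2,3,4,5+), and missingness counts.
    Variables with no estimable test carry NaN statistics, never abort.
    """
    rows = []

    def add(section, variable, case_val, noncase_val, stat=None, df=None, p=None):
        rows.append(
            {
                "section": section,
                "variable": variable,
                "cases": case_val,
                "noncases": noncase_val,
                "statistic": np.nan if stat is None else stat,
                "df": np.nan if df is None else df,
                "p": np.nan if p is None else p,
            }
        )

    add("totals", "n_reports", len(cases), len(noncases))

    # --- sex (complete cases) ---
    cf = sum(1 for r in cases if r.sex == "F")
    cm = sum(1 for r in cases if r.sex == "M")
    nf = sum(1 for r in noncases if r.sex == "F")
    nm = sum(1 for r in noncases if r.sex == "M")
    try:
        stat, df_, p = pearson_chi2([[cf, cm], [nf, nm]])
    except ValueError:
        stat = df_ = p = None
    add("sex", "female", cf, nf, stat, df_, p)
    add("sex", "male", cm, nm)
    add("missingness", "sex_missing", len(cases) - cf - cm, len(noncases) - nf - nm)

    # --- age (complete cases, pooled-variance t) ---
    ca = [r.age_years for r in cases if r.age_years is not None]
    na = [r.age_years for r in noncases if r.age_years is not None]
    if len(ca) >= 2 and len(na) >= 2 and np.std(ca, ddof=1) > 0 and np.std(na, ddof=1) > 0:
        t, df_, p = two_sample_t_equal_var(
            float(np.mean(ca)), float(np.std(ca, ddof=1)), len(ca),
            float(np.mean(na)), float(np.std(na, ddof=1)), len(na),
        )
    else:
        t = df_ = p = None
    add(
        "age",
        "mean_sd_n",
        f"{np.mean(ca):.2f} ± {np.std(ca, ddof=1):.1f} (n={len(ca)})" if ca else "not estimable",
        f"{np.mean(na):.2f} ± {np.std(na, ddof=1):.1f} (n={len(na)})" if na else "not estimable",
        t,
        df_,
        p,
    )
    add("missingness", "age_missing", len(cases) - len(ca), len(noncases) - len(na))

    # --- outcomes, outcome-present denominators ---
    cases_out = [r for r in cases if r.outcomes]
    noncases_out = [r for r in noncases if r.outcomes]
    add("outcome", "outcome_present", len(cases_out), len(noncases_out))
    outcome_names = sorted({o for r in cases_out + noncases_out for o in r.outcomes})
    if not outcome_names:
        add("outcome", "any", "not estimable", "not estimable")
    for name in outcome_names:
        cy = sum(1 for r in cases_out if name in r.outcomes)
        ny = sum(1 for r in noncases_out if name in r.outcomes)
        table = [[cy, len(cases_out) - cy], [ny, len(noncases_out) - ny]]
        try:
            stat, df_, p = pearson_chi2(table)
        except ValueError:
            stat = df_ = p = None
        add("outcome", name, cy, ny, stat, df_, p)
    add(
        "missingness",
        "outcome_missing",
        len(cases) - len(cases_out),
        len(noncases) - len(noncases_out),
    )

    # --- suspected drugs per report, bins 1..4 and 5+ ---
    def bins(reports):
        counts = [0] * 5
        for r in reports:
            counts[min(len(r.drugs), 5) - 1] += 1
        return counts

    cb, nb = bins(cases), bins(noncases)
    obs = [
        [c for c, n_ in zip(cb, nb) if c + n_ > 0],
        [n_ for c, n_ in zip(cb, nb) if c + n_ > 0],
    ]
    try:
        stat, df_, p = pearson_chi2(obs) if len(obs[0]) >= 2 else (None, None, None)
    except ValueError:
        stat = df_ = p = None
    labels = ["1", "2", "3", "4", "5+"]
    add("drugs_per_report", labels[0], cb[0], nb[0], stat, df_, p)
    for lab, c, n_ in zip(labels[1:], cb[1:], nb[1:]):
        add("drugs_per_report", lab, c, n_)

    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> RunSummary:
    """Execute the whole case/non-case pipeline and persist its artifacts.

    Writes results.tsv, descriptives.tsv, sampled_noncase_ids.txt and
    manifest.json into ``config.output_dir``.  Any stage failure aborts
    with the stage named; a partial directory carries no manifest and must
    be treated as invalid.
    """
    config.validate()
    out = Path(config.output_dir)

    stage = "load"
    try:
        reports = read_reports(config.reports_path)
        date_from = dt.date.fromisoformat(config.date_from) if config.date_from else None
        date_to = dt.date.fromisoformat(config.date_to) if config.date_to else None
        n_before = len(reports)
        reports = filter_by_date_window(reports, date_from, date_to)
        logger.info("date window: %d reports in, %d kept", n_before, len(reports))

        stage = "classify"
        smq = load_smq(config.smq_path, name=config.smq_name, scope=config.smq_scope)
        cases, noncase_pool = classify_all(reports, smq)
        logger.info("classified %d cases / %d non-cases", len(cases), len(noncase_pool))

        stage = "sample"
        sampled = sample_noncases(noncase_pool, len(cases), config.ratio, config.seed)

        stage = "summarize"
        descriptives = summarize_cohort(cases, sampled)

        stage = "build"
        rules = (
            load_combination_rules(config.combinations_path)
            if config.combinations_path
            else []
        )
        mentions = expand_mentions(cases, sampled, rules)
        logger.info(
            "mentions: %d case / %d non-case (%d unclassified ATC5)",
            mentions.n_case_mentions,
            mentions.n_noncase_mentions,
            mentions.n_unclassified,
        )

        stage = "estimate"
        criteria = config.criteria
        result_rows, skipped = [], []
        for level in config.levels:
            comparator = config.comparator_by_level.get(level, "all_other")
            eligible = filter_min_cases(mentions, level, config.min_cases)
            logger.info(
                "level %d: %d eligible entities (min %d case mentions)",
                level,
                len(eligible),
                config.min_cases,
            )
            for entity in eligible["entity"]:
                try:
                    table = build_table(mentions, str(entity), level, comparator)
                except DegenerateComparatorError as exc:
                    skipped.append((str(entity), level, str(exc)))
                    logger.warning("skipping %s at level %d: %s", entity, level, exc)
                    continue
                res = analyze_table(table, criteria, z=config.z)
                result_rows.append(
                    {
                        "entity": res.entity,
                        "level": res.level,
                        "comparator": res.comparator,
                        "a": res.a,
                        "b": res.b,
                        "c": res.c,
                        "d": res.d,
                        "corrected": res.corrected,
                        "ror": _fmt(res.ror, 2),
                        "ci_low": _fmt(res.ci_low, 2),
                        "ci_high": _fmt(res.ci_high, 2),
                        "n_case_mentions": res.n_case_mentions,
                        "signal": res.signal,
                    }
                )
        results = pd.DataFrame(result_rows, columns=RESULT_COLUMNS)

        stage = "persist"
        results.to_csv(out / "results.tsv", sep="\t", index=False)
        descriptives.to_csv(out / "descriptives.tsv", sep="\t", index=False)
        (out / "sampled_noncase_ids.txt").write_text(
            "".join(f"{r.report_id}\n" for r in sampled), encoding="utf-8"
        )
        from pvsignal import __version__ as pkg_version

        manifest = {
            "package_version": pkg_version,
            "config": config.to_dict(),
            "inputs": {
                "reports_sha256": _sha256(config.reports_path),
                "smq_sha256": _sha256(config.smq_path),
                "combinations_sha256": (
                    _sha256(config.combinations_path) if config.combinations_path else None
                ),
            },
            "totals": {
                "n_reports": len(reports),
                "n_cases": len(cases),
                "n_noncases_pool": len(noncase_pool),
                "n_noncases_sampled": len(sampled),
                "case_proportion_pct_full": proportion(len(cases), len(reports)),
                "case_proportion_pct_analysed": proportion(
                    len(cases), len(cases) + len(sampled)
                ),
                "n_case_mentions": mentions.n_case_mentions,
                "n_noncase_mentions": mentions.n_noncase_mentions,
                "n_unclassified_atc5": mentions.n_unclassified,
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return RunSummary(
        n_reports=len(reports),
        n_cases=len(cases),
        n_noncases_pool=len(noncase_pool),
        n_noncases_sampled=len(sampled),
        case_proportion_pct=proportion(len(cases), len(reports)),
        descriptives=descriptives,
        results=results,
        signals=sorted(results.loc[results["signal"], "entity"].tolist()),
        skipped_entities=skipped,
    )
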