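"""End-to-end orchestration of both fraud classifiers plus the comparison.

``run_pipeline`` reproduces the two-system study design: the multilayer
method (real-time rules, then the post hoc k-strike stage on survivors)
and the platform-score method applied independently to *all* responses.
The resulting :class:`PipelineReport` carries the flowchart counts, the
confusion matrix and kappa per survey-type stratum, subgroup outcome
estimates, and a windowed fraud-proportion time series.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import agreement
from .agreement import ConfusionMatrix2x2, KappaResult, SubgroupEstimate
from .platform import PlatformResult, PlatformThresholds, classify_platform_batch
from .posthoc import PosthocResult, apply_posthoc_stage
from .realtime import RealtimeResult, apply_realtime_stage
from .types import (
    ClassificationRecord,
    Config,
    Gazetteer,
    Label,
    Method,
    RuleFlag,
    RuleId,
    Stage,
    SurveyResponse,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    """All counts and statistics from one end-to-end run."""

    n_total: int
    realtime_fraud: int
    realtime_by_rule: Dict[str, int]
    posthoc_strike_counts: Dict[str, int]
    posthoc_fraud: int
    multilayer_valid: int
    platform_by_rule: Dict[str, int]
    platform_fraud: int
    platform_valid: int
    confusion: Dict[str, ConfusionMatrix2x2]
    kappa: Dict[str, Optional[KappaResult]]
    subgroup_tables: Dict[str, List[SubgroupEstimate]] = field(default_factory=dict)
    series: Optional[pd.DataFrame] = None
    multilayer_labels: Dict[str, Label] = field(default_factory=dict)
    platform_labels: Dict[str, Label] = field(default_factory=dict)
    multilayer_records: List[ClassificationRecord] = field(default_factory=list)

    @property
    def multilayer_fraud(self) -> int:
        return self.realtime_fraud + self.posthoc_fraud

    def to_dict(self) -> dict:
        """JSON-serializable summary (omits the per-response label maps)."""
        def kappa_dict(k: Optional[KappaResult]):
            if k is None:
                return None
            lk, mh = agreement.interpret_kappa(k.kappa)
            return {
                "kappa": k.kappa, "po": k.po, "pe": k.pe, "se": k.se,
                "ci_low": k.ci_low, "ci_high": k.ci_high,
                "confidence": k.confidence,
                "landis_koch": lk, "mchugh": mh,
            }

        return {
            "n_total": self.n_total,
            "realtime_fraud": self.realtime_fraud,
            "realtime_by_rule": self.realtime_by_rule,
            "posthoc_strike_counts": self.posthoc_strike_counts,
            "posthoc_fraud": self.posthoc_fraud,
            "multilayer_fraud": self.multilayer_fraud,
            "multilayer_valid": self.multilayer_valid,
            "multilayer_valid_pct": round(100.0 * self.multilayer_valid / self.n_total, 2),
            "platform_by_rule": self.platform_by_rule,
            "platform_fraud": self.platform_fraud,
            "platform_valid": self.platform_valid,
            "confusion": {
                stratum: {"a": cm.a, "b": cm.b, "c": cm.c, "d": cm.d, "n": cm.n}
                for stratum, cm in self.confusion.items()
            },
            "kappa": {s: kappa_dict(k) for s, k in self.kappa.items()},
            "subgroup_tables": {
                name: [est.__dict__ for est in table]
                for name, table in self.subgroup_tables.items()
            },
            "series": (
                None if self.series is None
                else {
                    "dates": [d.strftime("%Y-%m-%d") for d in self.series.index],
                    **{
                        col: [None if pd.isna(v) else round(float(v), 4)
                              for v in self.series[col]]
                        for col in self.series.columns
                    },
                }
            ),
        }


def run_pipeline(
    responses: List[SurveyResponse],
    gazetteer: Gazetteer,
    cfg: Optional[Config] = None,
    window_days: int = 7,
) -> PipelineReport:
    """Run both classifiers over a batch and assemble the full report.

    The platform classification covers all responses; the post hoc stage
    sees only stage-1 survivors.  Every response ends in exactly one of
    {realtime fraud, posthoc fraud, multilayer valid}.
    """
    cfg = cfg or Config()
    n = len(responses)
    by_id = {r.response_id: r for r in responses}

    stage1: RealtimeResult = apply_realtime_stage(responses, gazetteer, cfg)
    survivors = [r for r in responses if stage1.labels[r.response_id] is Label.VALID]
    logger.info("stage 1: %d/%d fraud", len(stage1.fraud_ids), n)

    stage2: PosthocResult = apply_posthoc_stage(survivors, gazetteer, cfg)
    logger.info("stage 2: %d/%d fraud", len(stage2.fraud_ids), len(survivors))

    multilayer_labels: Dict[str, Label] = {}
    multilayer_records: List[ClassificationRecord] = []
    for r in responses:
        rid = r.response_id
        if stage1.labels[rid] is Label.FRAUD:
            label, stage = Label.FRAUD, Stage.REALTIME
            flags = [f for f in stage1.flags if f.response_id == rid]
        elif stage2.labels[rid] is Label.FRAUD:
            label, stage = Label.FRAUD, Stage.POSTHOC
            flags = [RuleFlag(rid, rule) for rule in sorted(stage2.strikes[rid], key=lambda x: x.value)]
        else:
            label, stage, flags = Label.VALID, Stage.NONE, []
        multilayer_labels[rid] = label
        multilayer_records.append(
            ClassificationRecord(rid, Method.MULTILAYER, label, stage, flags)
        )

    platform: PlatformResult = classify_platform_batch(
        responses, PlatformThresholds.from_config(cfg)
    )
    platform_labels = platform.labels

    strata: Dict[str, List[str]] = {"full": [r.response_id for r in responses]}
    for r in responses:
        strata.setdefault(r.survey_type.value, []).append(r.response_id)

    confusion: Dict[str, ConfusionMatrix2x2] = {}
    kappa: Dict[str, Optional[KappaResult]] = {}
    for stratum, ids in strata.items():
        cm = agreement.build_confusion(
            {i: multilayer_labels[i] for i in ids},
            {i: platform_labels[i] for i in ids},
        )
        confusion[stratum] = cm
        try:
            kappa[stratum] = agreement.cohen_kappa(cm)
        except Exception:
            logger.info("kappa not computable for stratum %r (degenerate marginals)", stratum)
            kappa[stratum] = None

    subgroup_tables = _subgroup_tables(responses, multilayer_labels, platform_labels)

    series = agreement.fraud_proportion_series(
        {r.response_id: pd.Timestamp(r.start_time) for r in responses},
        {"multilayer": multilayer_labels, "platform": platform_labels},
        window_days=window_days,
    )

    report = PipelineReport(
        n_total=n,
        realtime_fraud=len(stage1.fraud_ids),
        realtime_by_rule={k.value: v for k, v in stage1.counts_by_rule.items()},
        posthoc_strike_counts={k.value: v for k, v in stage2.strike_counts().items()},
        posthoc_fraud=len(stage2.fraud_ids),
        multilayer_valid=sum(1 for lab in multilayer_labels.values() if lab is Label.VALID),
        platform_by_rule={k.value: v for k, v in platform.counts_by_rule.items()},
        platform_fraud=platform.fraud_count,
        platform_valid=n - platform.fraud_count,
        confusion=confusion,
        kappa=kappa,
        subgroup_tables=subgroup_tables,
        series=series,
        multilayer_labels=multilayer_labels,
        platform_labels=platform_labels,
        multilayer_records=multilayer_records,
    )
    assert report.multilayer_valid == n - report.realtime_fraud - report.posthoc_fraud
    return report


def _subgroup_tables(responses, multilayer_labels, platform_labels):
    """Outcome mean +/- normal CI by race/ethnicity within each valid set."""
    values: Dict[str, float] = {}
    groups: Dict[str, str] = {}
    for r in responses:
        v = r.outcome_answers.get("vaccine_confidence")
        g = r.demographics.get("race_ethnicity")
        if v is None or g is None:
            continue
        try:
            values[r.response_id] = float(v)
        except ValueError:
            continue
        groups[r.response_id] = str(g)
    if not values:
        return {}
    tables = {}
    for name, labels in (("multilayer_valid", multilayer_labels),
                         ("platform_valid", platform_labels)):
        keep = {rid for rid, lab in labels.items() if lab is Label.VALID}
        sub_vals = {rid: v for rid, v in values.items() if rid in keep}
        if sub_vals:
            tables[name] = agreement.evaluate_by_subgroup(
                sub_vals, {rid: groups[rid] for rid in sub_vals}
            )
    return tables


def write_labels_csv(path, records: List[ClassificationRecord]) -> None:
    """Write per-response labels: response_id,label,stage,rules."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(("response_id", "label", "stage", "rules"))
        for rec in records:
            rules = ";".join(f.rule_id.value for f in rec.flags)
            w.writerow((rec.response_id, rec.label.value, rec.stage.value, rules))


def read_labels_csv(path) -> Dict[str, Label]:
    """Read a labels CSV back into a response_id -> Label map."""
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        return {row["response_id"]: Label(row["label"]) for row in csv.DictReader(fh)}


def write_report(path, report: PipelineReport) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8")
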