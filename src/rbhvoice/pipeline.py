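"""End-to-end orchestration: per-recording analysis and study-level runs.

A study takes a manifest (audio + optional EGG + alignment per recording,
plus a ratings table), extracts one feature vector per recording, computes
the interrater-agreement report, and fits one rating model per criterion
(CFS selection in cross-validation, then SMO-SVR), evaluating each against
the item-averaged ratings.  All outputs are written deterministically so a
rerun with the same manifest, config and seed is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agreement_mod
from . import egg as egg_mod
from . import model as model_mod
from . import prosody
from .config import AnalysisConfig
from .errors import RbhVoiceError, UndefinedValueError, ValidationError
from .f0 import analyze_track, segment_sections
from .io import (CRITERIA, FeatureTable, Recording, WordAlignment,
                 read_alignment, read_ratings, read_recording,
                 write_feature_table)

log = logging.getLogger("rbhvoice")


def analyze_recording(recording: Recording, alignment: WordAlignment,
                      config: AnalysisConfig | None = None
                      ) -> tuple[pd.Series, egg_mod.EggSummary | None, dict]:
    """Full single-recording chain: F0 track, prosodic features, EGG measures.

    Returns the aggregated feature vector, the EGG summary (None without an
    EGG channel) and a dict of diagnostic counts.
    """
    cfg = config or AnalysisConfig()
    track = analyze_track(recording, cfg.framing, cfg.voicing)
    local = prosody.extract_local(recording, alignment, track, cfg.prosody)
    global_ = prosody.extract_global(recording, alignment, track, cfg.prosody)
    summary = None
    if recording.egg is not None:
        try:
            _, summary = egg_mod.analyze_egg(recording.egg,
                                             recording.egg_sample_rate, cfg.egg)
        except UndefinedValueError as exc:
            log.warning("%s: EGG analysis yielded no cycles (%s)", recording.id, exc)
    vector = prosody.aggregate(local, global_, summary)
    sections = segment_sections(track)
    counts = {
        "words": len(local),
        "windows": len(global_),
        "voiced_sections": sections.count(True),
        "cycles": summary.n_cycles if summary is not None else 0,
    }
    log.info("%s: %s", recording.id, counts)
    return vector, summary, counts


@dataclass
class ManifestEntry:
    id: str
    audio: str
    alignment: str
    egg: str | None = None
    dialect: str | None = None  # inferred from the extension when None


@dataclass
class StudyManifest:
    recordings: list[ManifestEntry]
    ratings: str
    base_dir: Path = Path(".")

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyManifest":
        path = Path(path)
        doc = json.loads(path.read_text(encoding="utf-8"))
        entries = [ManifestEntry(**e) for e in doc["recordings"]]
        ids = [e.id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate recording ids in manifest")
        return cls(entries, doc["ratings"], base_dir=path.parent)

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


def _infer_dialect(path: str) -> str:
    return "textgrid" if path.lower().endswith(".textgrid") else "ctm"


def build_feature_table(manifest: StudyManifest,
                        config: AnalysisConfig | None = None) -> FeatureTable:
    """Analyze every manifest recording into one feature table."""
    rows = {}
    for entry in manifest.recordings:
        try:
            rec = read_recording(manifest.resolve(entry.audio),
                                 egg_path=(manifest.resolve(entry.egg)
                                           if entry.egg else None),
                                 rec_id=entry.id)
            alignment = read_alignment(
                manifest.resolve(entry.alignment),
                dialect=entry.dialect or _infer_dialect(entry.alignment))
            vector, _, _ = analyze_recording(rec, alignment, config)
        except RbhVoiceError as exc:
            raise type(exc)(f"recording {entry.id!r}: {exc}") from exc
        rows[entry.id] = vector
    return FeatureTable(pd.DataFrame(rows).T)


@dataclass
class CriterionResult:
    criterion: str
    selected: list[str]
    ranked: list[str]
    frequencies: dict[str, float]
    model: model_mod.RegressionModel
    predictions: np.ndarray
    r: float
    rho: float
    p: float


@dataclass
class StudyReport:
    feature_table: FeatureTable
    agreement: agreement_mod.AgreementReport
    results: dict[str, CriterionResult]
    correlation_matrix: pd.DataFrame  # Pearson upper / Spearman lower triangle

    def to_dict(self) -> dict:
        return {
            "agreement": {
                "summary": self.agreement.summary,
                "cross": {f"{a}-{b}": v for (a, b), v in self.agreement.cross.items()},
            },
            "models": {
                c: {
                    "selected": res.selected,
                    "weights": {f: w for f, w in
                                zip(res.model.feature_names,
                                    res.model.weights.tolist())},
                    "intercept": res.model.intercept,
                    "r": res.r, "rho": res.rho, "p": res.p,
                }
                for c, res in self.results.items()
            },
        }


def mixed_correlation_matrix(table: FeatureTable, columns: list[str]
                             ) -> pd.DataFrame:
    """Pearson r in the upper-right triangle, Spearman rho in the lower-left."""
    out = pd.DataFrame(np.nan, index=columns, columns=columns)
    for i, a in enumerate(columns):
        for j, b in enumerate(columns):
            if i == j:
                continue
            x, y = table.data[a], table.data[b]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            if i < j:
                out.iloc[i, j], _ = agreement_mod.pearson(x[ok], y[ok])
            else:
                out.iloc[i, j], _ = agreement_mod.spearman(x[ok], y[ok])
    return out


def run_modeling(table: FeatureTable, targets: dict[str, np.ndarray],
                 config: AnalysisConfig | None = None, seed: int = 0
                 ) -> dict[str, CriterionResult]:
    """CFS selection + SMO-SVR + evaluation, one model per target criterion."""
    cfg = (config or AnalysisConfig()).model
    n = len(table.rows)
    if n < cfg.folds:
        raise ValidationError(
            f"{n} rated recordings cannot fill {cfg.folds} folds; "
            "reduce model.folds in the config")
    # complete-case design matrix: impute residual missing values by column mean
    data = table.data.copy()
    data = data.fillna(data.mean())
    filled = FeatureTable(data)
    results = {}
    for criterion, target in targets.items():
        selection = model_mod.cfs_select(filled, target, folds=cfg.folds,
                                         seed=seed, stall_limit=cfg.stall_limit)
        selected = selection.selected(cfg.min_frequency)
        fitted = model_mod.train_svr(filled, target, selected,
                                     C=cfg.C, epsilon=cfg.epsilon, tol=cfg.tol)
        predictions = fitted.predict(filled)
        r, rho, p = model_mod.evaluate(predictions, target)
        results[criterion] = CriterionResult(
            criterion=criterion, selected=selected,
            ranked=selection.ranked_features,
            frequencies=selection.frequencies,
            model=fitted, predictions=predictions, r=r, rho=rho, p=p)
    return results


def run_study(manifest: StudyManifest, config: AnalysisConfig | None = None,
              seed: int = 0, out_dir: str | Path | None = None) -> StudyReport:
    """Whole-study pipeline: features, agreement, one model per criterion."""
    cfg = config or AnalysisConfig()
    table = build_feature_table(manifest, cfg)
    panel = read_ratings(manifest.resolve(manifest.ratings))
    common = [r for r in table.rows if r in panel.items]
    if len(common) < len(table.rows):
        log.warning("%d recordings lack ratings", len(table.rows) - len(common))
    table = FeatureTable(table.data.loc[common])
    item_pos = [panel.items.index(r) for r in common]
    targets = {c: panel.item_means(c)[item_pos] for c in CRITERIA}
    results = run_modeling(table, targets, cfg, seed)
    report = StudyReport(
        feature_table=table,
        agreement=agreement_mod.panel_summary(panel),
        results=results,
        correlation_matrix=mixed_correlation_matrix(
            table, sorted({f for res in results.values() for f in res.selected})),
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write the report files plus a checksum manifest, deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_feature_table(report.feature_table, out / "features.tsv")
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    report.correlation_matrix.to_csv(out / "correlations.tsv", sep="\t",
                                     float_format="%.6g")
    tables = report.agreement.summary_table() + "\n\n" + \
        report.agreement.cross_table() + "\n"
    (out / "agreement.txt").write_text(tables, encoding="utf-8")
    checksums = []
    for name in ("features.tsv", "report.json", "correlations.tsv",
                 "agreement.txt"):
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        checksums.append(f"{digest}  {name}")
    (out / "checksums.txt").write_text("\n".join(checksums) + "\n",
                                       encoding="utf-8")
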