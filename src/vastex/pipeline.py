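"""End-to-end orchestration: simulate -> features -> screen -> classify -> evaluate.

Every stage writes a plain CSV artifact so each can also be re-run standalone
from the previous stage's files; a fixed global seed makes the whole report
bundle reproducible byte-for-byte (run.log, which records wall-clock stage
timings, is the only non-deterministic file).
"""

from __future__ import annotations

import hashlib
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .cohort import (CohortConfig, cohort_class_summary, features_table,
                     generate_cohort)
from .evaluate import evaluate_all
from .screening import screen
from .texture import FeatureConfig

ARTIFACTS = ("manifest.csv", "features.csv", "screening.csv",
             "class_summary.csv", "predictions.csv", "metrics.csv",
             "auroc.csv", "roc_points.csv", "report.md")


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run: cohort design, feature settings,
    screening level, classifier settings and the global seed."""

    cohort: CohortConfig = CohortConfig()
    features: FeatureConfig = FeatureConfig()
    q: float = 0.05
    svm_kernel: str = "rbf"
    svm_penalty: float = 1.0
    knn_k: int = 5
    seed: int = 0

    def resolved_cohort(self) -> CohortConfig:
        """Cohort config with the global seed applied."""
        d = asdict(self.cohort)
        d["seed"] = self.seed
        for key in ("normal", "abnormal"):
            d[key] = getattr(self.cohort, key)
        return CohortConfig(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "cohort" in d:
            c = d["cohort"]
            for key in ("normal", "abnormal"):
                if key in c and isinstance(c[key], dict):
                    from .cohort import ClassParams
                    c[key] = ClassParams(**c[key])
            d["cohort"] = CohortConfig(**c)
        if "features" in d:
            d["features"] = FeatureConfig(**d["features"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def write(self, msg: str) -> None:
        line = msg.rstrip()
        self.lines.append(line)
        print(line, file=sys.stderr)
        self.path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage and write the report bundle into ``out_dir``.

    Returns a dict with the in-memory stage products (cohort, features,
    screening, metrics, auroc table, reports).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    config.to_yaml(out / "config.yaml")
    log.write(f"run config digest {config.digest()} seed {config.seed}")

    def stage(name):
        log.write(f"[{name}] start")
        t0 = time.perf_counter()
        return lambda: log.write(f"[{name}] done in {time.perf_counter() - t0:.1f} s")

    done = stage("simulate")
    cohort = generate_cohort(config.resolved_cohort())
    manifest = pd.DataFrame(
        [(s.subject, s.label, s.role, len(s.frames)) for s in cohort.samples],
        columns=["subject", "class", "role", "n_frames"],
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    done()

    done = stage("features")
    feats = features_table(cohort, config.features)
    feats.to_csv(out / "features.csv", index=False)
    summary = cohort_class_summary(feats)
    flat = summary.copy()
    flat.columns = ["_".join(c) for c in flat.columns]
    flat.to_csv(out / "class_summary.csv")
    done()

    done = stage("screen")
    screening = screen(feats, q=config.q)
    screening.table.to_csv(out / "screening.csv")
    done()

    done = stage("classify+evaluate")
    metrics, roc_points, predictions, reports = evaluate_all(
        feats, screening,
        svm_kwargs={"kernel": config.svm_kernel, "penalty": config.svm_penalty},
        knn_kwargs={"k": config.knn_k},
    )
    predictions.to_csv(out / "predictions.csv", index=False)
    metrics.to_csv(out / "metrics.csv", index=False)
    auroc = metrics[["feature_set", "classifier", "auroc"]]
    auroc.to_csv(out / "auroc.csv", index=False)
    roc_points.to_csv(out / "roc_points.csv", index=False)
    done()

    make_report(out)
    log.write(f"selected features: {', '.join(screening.selected)}")
    return {"cohort": cohort, "features": feats, "screening": screening,
            "summary": summary, "metrics": metrics, "auroc": auroc,
            "reports": reports}


def make_report(out_dir) -> str:
    """Render a markdown summary of a completed bundle; returns the text."""
    out = Path(out_dir)
    needed = ["manifest.csv", "features.csv", "screening.csv", "metrics.csv"]
    for name in needed:
        if not (out / name).exists():
            raise FileNotFoundError(f"missing pipeline artifact: {out / name}")
    manifest = pd.read_csv(out / "manifest.csv")
    screening = pd.read_csv(out / "screening.csv", index_col=0)
    metrics = pd.read_csv(out / "metrics.csv")
    selected = screening.index[screening["significant"]].tolist()
    lines = [
        "# Pipeline report",
        "",
        f"Cohort: {len(manifest)} ROIs "
        f"({(manifest['class'] == 'normal').sum()} normal, "
        f"{(manifest['class'] == 'abnormal').sum()} abnormal); "
        f"{(manifest['role'] == 'train').sum()} train / "
        f"{(manifest['role'] == 'test').sum()} test.",
        "",
        "## Feature screening (per-subject means, BH-FDR)",
        "",
        screening.round(6).to_markdown(),
        "",
        f"Selected ({len(selected)}): {', '.join(selected)}",
        "",
        "## Classifier performance on the held-out split",
        "",
        metrics.round(4).to_markdown(index=False),
        "",
    ]
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
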