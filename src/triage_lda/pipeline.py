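"""Experiment orchestration: feature variants x coherence measures x triage.

``run_experiment`` executes preprocess -> enrich -> fit -> coherence ->
cross-validated triage for each requested feature variant and writes a
report bundle (coherence table, accuracy table, manifest). The manifest
records every seed and parameter plus input hashes; re-running from a
manifest reproduces every report cell bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coherence as coh
from .enrichment import VARIANTS, annotate, build_bow, match_concepts, read_lexicon
from .io import read_corpus
from .textprep import Mode, prepare, read_variant_lexicon
from .topic_model import fit_lda
from .triage import TREATMENTS, crossval_knn, make_dataset

log = logging.getLogger("triage_lda")

COHERENCE_MEASURES = ("c_uci", "c_npmi", "c_umass", "c_v")


@dataclass
class ExperimentConfig:
    corpus: str
    concept_lexicon: str
    variant_lexicon: str | None = None
    variants: tuple[str, ...] = ("D1", "D2", "D3", "D4")
    mode: str = "stem"
    k: int = 11
    measures: tuple[str, ...] = COHERENCE_MEASURES
    top_n: int = 10
    window: int = 8
    min_df: int = 1
    iterations: int = 400
    burn_in: int = 200
    knn_k: int = 5
    folds: int = 10
    seed: int = 7
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("at least one feature variant is required")
        unknown = [v for v in self.variants if v.upper() not in VARIANTS]
        if unknown:
            raise ValueError(f"unknown variants: {unknown}")
        Mode(self.mode)  # validates
        for path in (self.corpus, self.concept_lexicon, self.variant_lexicon):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        for key in ("variants", "measures"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full grid; returns the report dict and writes the bundle."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    letters, labels = read_corpus(cfg.corpus)
    variant_lex = (
        read_variant_lexicon(cfg.variant_lexicon) if cfg.variant_lexicon else None
    )
    lexicon = read_lexicon(cfg.concept_lexicon)
    log.info("stage=load docs=%d labeled=%d", len(letters), len(labels))

    base_streams = [prepare(l, lex=variant_lex, mode=cfg.mode) for l in letters]
    log.info("stage=prep done elapsed=%.1fs", time.time() - t0)

    coherence_rows = []
    accuracy_rows = []
    errors: dict[str, str] = {}
    for variant in cfg.variants:
        try:
            streams = [
                annotate(s, match_concepts(s, lexicon, window=cfg.window), variant)
                for s in base_streams
            ]
            bow = build_bow(streams, min_df=cfg.min_df)
            model = fit_lda(
                bow, cfg.k, iterations=cfg.iterations, burn_in=cfg.burn_in,
                seed=cfg.seed,
            )
            row = {"variant": variant}
            for measure in cfg.measures:
                ccfg = coh.CoherenceConfig(measure=measure, top_n=cfg.top_n)
                stats = coh.stats_for_model(model, streams, ccfg)
                row[measure] = coh.topic_coherence(model, stats, ccfg).mean
            coherence_rows.append(row)
            log.info("stage=coherence variant=%s done", variant)

            if labels:
                ds = make_dataset(model, streams, labels)
                for t in TREATMENTS:
                    res = crossval_knn(
                        ds, t, k=cfg.knn_k, folds=cfg.folds, seed=cfg.seed
                    )
                    accuracy_rows.append(
                        {
                            "treatment": t,
                            "variant": variant,
                            "accuracy": res.mean_accuracy,
                            "baseline": res.baseline_accuracy,
                        }
                    )
                log.info("stage=triage variant=%s done", variant)
        except Exception as exc:  # partial results are preserved
            errors[variant] = f"{type(exc).__name__}: {exc}"
            log.error("stage=variant variant=%s failed error=%s", variant, exc)

    coherence_df = pd.DataFrame(coherence_rows)
    coherence_df.to_csv(out / "coherence.csv", index=False, float_format="%.12g")
    report = {"coherence": coherence_rows, "errors": errors}
    if accuracy_rows:
        acc_df = pd.DataFrame(accuracy_rows).pivot(
            index="treatment", columns="variant", values="accuracy"
        )
        acc_df["baseline"] = (
            pd.DataFrame(accuracy_rows).groupby("treatment")["baseline"].first()
        )
        acc_df.to_csv(out / "accuracy.csv", float_format="%.12g")
        report["accuracy"] = accuracy_rows

    manifest = {
        "config": asdict(cfg),
        "input_hashes": {
            "corpus": _sha256(cfg.corpus),
            "concept_lexicon": _sha256(cfg.concept_lexicon),
            "variant_lexicon": _sha256(cfg.variant_lexicon)
            if cfg.variant_lexicon
            else None,
        },
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), "utf-8")
    log.info("stage=report written=%s elapsed=%.1fs", out, time.time() - t0)
    return report


def run_from_manifest(manifest_path, out_dir=None) -> dict:
    """Re-run an experiment exactly as recorded in a manifest."""
    manifest = json.loads(Path(manifest_path).read_text("utf-8"))
    data = dict(manifest["config"])
    for key in ("variants", "measures"):
        data[key] = tuple(data[key])
    if out_dir is not None:
        data["out_dir"] = str(out_dir)
    cfg = ExperimentConfig(**data)
    for name, recorded in manifest["input_hashes"].items():
        if recorded is None:
            continue
        path = getattr(cfg, name if name != "corpus" else "corpus")
        actual = _sha256(path)
        if actual != recorded:
            raise ValueError(f"input {name} changed since the manifest was written")
    return run_experiment(cfg)
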