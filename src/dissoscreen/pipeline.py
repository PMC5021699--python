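"""End-to-end screening pipeline: generate/load -> score -> test -> classify.

Stages run in the fixed methodological order: phrases are scored on the
three channels, the per-group chi-square dissociation report is
produced, and only then is the classifier ablation run.  The
dissociation check is advisory — its outcome is logged, never used to
block classification.  Every run writes a manifest (config snapshot,
seeds, package version, input digests, per-stage row counts) and is a
pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .classify import ablation_study, build_training_file
from .dissociation import dissociation_report
from .orientation import (DEFAULT_SMOOTHING, DEFAULT_THRESHOLD, count_corpus,
                          read_corpus, semantic_orientation)
from .polarity import Lexicon, load_default_lexicon, load_lexicon
from .records import write_training_csv
from .synth import SynthConfig, generate_dataset
from .tone import ToneBandMap, map_emotion

logger = logging.getLogger("dissoscreen")

__all__ = ["run_screening", "score_table", "load_config", "sha256_file"]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline config file."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)


def score_table(
    phrases: pd.DataFrame,
    lexicon: Lexicon,
    corpus: list[str] | None,
    band_map: ToneBandMap | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    smoothing: float = DEFAULT_SMOOTHING,
) -> pd.DataFrame:
    """Score a phrase table on all three channels.

    ``phrases`` needs columns ``phrase_id``, ``group``, ``text`` and
    either ``emotion`` (label) or ``tone_code`` (band).  Returns the
    table with ``polarity``, ``so``, ``so_code`` and ``tone_code``
    columns appended (``so_code`` is 0 when no corpus is supplied).
    """
    from .polarity import score_phrase, tokenize

    required = {"phrase_id", "group", "text"}
    missing = required - set(phrases.columns)
    if missing:
        raise ValueError(f"phrase table is missing columns {sorted(missing)}")
    out = phrases.copy()
    token_lists = [tokenize(t) for t in out["text"].astype(str)]
    out["polarity"] = [score_phrase(t, lexicon).scalar for t in token_lists]
    if corpus:
        stats = count_corpus(corpus, smoothing=smoothing)
        so_results = [semantic_orientation(t, stats, threshold=threshold)
                      for t in token_lists]
        out["so"] = [r.so for r in so_results]
        out["so_code"] = [r.so_code for r in so_results]
    else:
        out["so"] = 0.0
        out["so_code"] = 0
    if "tone_code" in out.columns and out["tone_code"].notna().all():
        out["tone_code"] = out["tone_code"].astype(int)
    elif "emotion" in out.columns:
        out["tone_code"] = [map_emotion(e, band_map)
                            for e in out["emotion"].astype(str)]
    else:
        raise ValueError("phrase table needs an 'emotion' or 'tone_code' "
                         "column")
    return out


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def run_screening(config: Mapping[str, Any], out_dir: str | Path) -> dict:
    """Run the whole pipeline and write all artifacts to ``out_dir``.

    Config keys (all optional): ``synth`` (generator settings; used
    when no ``phrases``/``corpus`` input paths are given), ``phrases``/
    ``corpus``/``lexicon_dir`` (input paths), ``tau`` (SO threshold,
    bits), ``smoothing``, ``folds``, ``seed``, ``alpha``, ``collapse``,
    ``positive_label``.  Returns the manifest dict (also written as
    ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "inputs": {},
        "stages": {},
    }

    if "lexicon_dir" in config:
        d = Path(config["lexicon_dir"])
        paths = (d / "sentiment.tsv", d / "boosters.tsv", d / "negators.txt")
        for p in paths:
            manifest["inputs"][p.name] = sha256_file(p)
        lexicon = load_lexicon(*paths)
    else:
        lexicon = load_default_lexicon()

    if "phrases" in config:
        for key in ("phrases", "corpus"):
            if key in config:
                manifest["inputs"][key] = sha256_file(config[key])
        phrases = pd.read_csv(config["phrases"])
        corpus = read_corpus(config["corpus"]) if "corpus" in config else None
    else:
        synth_cfg = SynthConfig(**{**config.get("synth", {}), "seed": seed})
        dataset = generate_dataset(synth_cfg, lexicon=lexicon)
        phrases, corpus = dataset.phrases, dataset.corpus
        phrases.to_csv(out / "phrases.csv", index=False)
        (out / "corpus.txt").write_text("\n".join(corpus) + "\n",
                                        encoding="utf-8")
        manifest["stages"]["generate"] = {
            "n_phrases": len(phrases),
            "n_corpus_docs": len(corpus),
            "synth_config": dataclasses.asdict(synth_cfg),
        }
    logger.info("scoring %d phrases", len(phrases))

    scored = score_table(phrases, lexicon, corpus,
                         threshold=float(config.get("tau",
                                                    DEFAULT_THRESHOLD)),
                         smoothing=float(config.get("smoothing",
                                                    DEFAULT_SMOOTHING)))
    scored.to_csv(out / "scored.csv", index=False)
    manifest["stages"]["score"] = {"n_phrases": len(scored)}

    training = scored.rename(columns={"group": "class"})
    records = build_training_file(training)
    write_training_csv(records, out / "training.csv")
    manifest["stages"]["training_file"] = {"n_records": len(records)}

    report = dissociation_report(records,
                                 alpha=float(config.get("alpha", 0.05)),
                                 collapse=bool(config.get("collapse", True)))
    (out / "dissociation.json").write_text(report.to_json() + "\n",
                                           encoding="utf-8")
    (out / "dissociation.txt").write_text(report.to_text() + "\n",
                                          encoding="utf-8")
    for g, pairs in report.per_group.items():
        for pair, res in pairs.items():
            verdict = ("association" if res.p_value < report.alpha
                       else "dissociation")
            logger.info("group %s %s: chi2=%.2f df=%d p=%.3g -> %s",
                        g, pair, res.statistic, res.df, res.p_value, verdict)
    manifest["stages"]["dissociation"] = {
        "groups": report.group_sizes,
        "p_values": {g: {p: res.p_value for p, res in pairs.items()}
                     for g, pairs in report.per_group.items()},
    }

    classes = {r.class_label for r in records}
    if len(classes) < 2:
        logger.warning("classification skipped: single class %s",
                       sorted(classes))
        manifest["stages"]["classify"] = {
            "skipped": f"single class {sorted(classes)}"}
    else:
        metrics = ablation_study(
            records,
            folds=int(config.get("folds", 10)),
            seed=seed,
            positive_label=str(config.get("positive_label", "case")),
        )
        (out / "metrics.json").write_text(metrics.to_json() + "\n",
                                          encoding="utf-8")
        (out / "metrics.txt").write_text(metrics.to_text() + "\n",
                                         encoding="utf-8")
        roc_rows = [
            {"feature_set": "+".join(r.feature_set), "classifier":
             r.classifier, "fpr": p[0], "tpr": p[1]}
            for r in metrics.rows for p in r.roc_points
        ]
        pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False)
        manifest["stages"]["classify"] = {"n_rows": len(metrics.rows)}

    _json_dump(manifest, out / "manifest.json")
    return manifest
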