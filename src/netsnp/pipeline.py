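"""End-to-end workflow orchestration with a single master seed.

Stages run in method order: compress (if the input is a VCF) -> cohort
filter/balance -> Fisher ranking -> network training -> holdout metrics
-> netSNP tSNP scoring -> classification against the random-SNP band ->
burden validation.  Every stage derives its own child seed from the
master seed and the stage name, so any stage can be replayed in
isolation, and every derived artifact lands in the run directory with
one structured log line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import burden as burden_mod
from .assoc import association_scan, rank_snps
from .cohorts import SplitSpec, balanced_split, filter_cohorts
from .engine import classify_tsnps, derive_seed, evaluate_tsnp, null_band_mcvt
from .metrics import accuracy, prevalence_metrics, roc_curve
from .network import NetConfig, build_feature_matrix, train_patternnet
from .store import GenotypeStore, SampleRecord, compress_vcf, read_metadata

logger = logging.getLogger("netsnp")


@dataclass
class PipelineConfig:
    store_path: str
    metadata_path: str
    n_train: int = 3200
    n_holdout: int = 1500
    validation_frac: float = 0.15
    top_k: int = 50
    exclude_genes: tuple[str, ...] = ()
    net: NetConfig = field(default_factory=NetConfig)
    n_reps: int = 20
    n_random: int = 1000
    null_reps: int = 5
    alpha: float = 0.05
    n_targets: int = 50
    prevalence_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))
    seed: int = 0


def _rows_for(store: GenotypeStore, sample_ids: Sequence[str]) -> np.ndarray:
    index = {s: i for i, s in enumerate(store.sample_ids)}
    return np.array([index[s] for s in sample_ids], dtype=int)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full workflow; returns a manifest of stage outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    manifest = {"config": _config_dict(config), "stages": {}}
    try:
        # -- load
        store_path = Path(config.store_path)
        records = read_metadata(config.metadata_path)
        if store_path.suffix == ".vcf":
            store = compress_vcf(store_path, records)
            store.to_nss(out / "store.nss")
            manifest["stages"]["compress"] = {"loci": store.n_loci}
        else:
            store = GenotypeStore.from_nss(store_path)
        logger.info("stage=load n_samples=%d n_loci=%d", store.n_samples, store.n_loci)

        # -- balance
        retained = filter_cohorts(records)
        split = balanced_split(records, retained, config.n_train,
                               config.n_holdout, config.validation_frac,
                               seed=derive_seed(config.seed, "split"))
        split.to_json(out / "split.json")
        manifest["stages"]["balance"] = {"retained_cohorts": sorted(retained),
                                         "train": len(split.train_ids),
                                         "holdout": len(split.holdout_ids)}
        by_id = {r.sample_id: r for r in records}
        train_rows = _rows_for(store, split.train_ids)
        val_rows = _rows_for(store, split.validation_ids)
        hold_rows = _rows_for(store, split.holdout_ids)
        y_train = np.array([by_id[s].status == "case" for s in split.train_ids])
        y_val = np.array([by_id[s].status == "case" for s in split.validation_ids])
        y_hold = np.array([by_id[s].status == "case" for s in split.holdout_ids])

        # -- rank
        ranked, assoc = rank_snps(store, train_rows, y_train,
                                  exclude_genes=config.exclude_genes,
                                  top_k=config.top_k)
        assoc.to_frame(store).to_csv(out / "assoc.tsv", sep="\t", index=False)
        manifest["stages"]["assoc"] = {"top_loci": [int(i) for i in ranked]}
        logger.info("stage=assoc top_k=%d best_fishp=%.3g",
                    config.top_k, float(assoc.fishp.min()))

        # -- train
        x_train, scaling = build_feature_matrix(store, train_rows, ranked)
        x_val = scaling.apply(store.feature_codes(val_rows, ranked))
        cfg = dataclasses.replace(config.net, seed=derive_seed(config.seed, "train"))
        net = train_patternnet(x_train, y_train.astype(int), x_val,
                               y_val.astype(int), cfg,
                               feature_loci=ranked, scaling=scaling)
        net.to_json(out / "net.json")
        manifest["stages"]["train"] = {"stop_reason": net.stop_reason,
                                       "epochs": len(net.history) - 1}

        # -- evaluate
        x_hold = scaling.apply(store.feature_codes(hold_rows, ranked))
        cv = net.predict_cv(x_hold)
        roc = roc_curve(cv + 0.5, y_hold.astype(int))
        metrics = {
            "accuracy_all": accuracy(cv, y_hold.astype(int)),
            "accuracy_outer_quartiles": accuracy(cv, y_hold.astype(int),
                                                 "outer_quantile", 0.5),
            "auc": roc.auc,
            "prevalence_sweep": prevalence_metrics(cv, y_hold.astype(int),
                                                   config.prevalence_grid),
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1, default=float)
        manifest["stages"]["eval"] = {"accuracy": metrics["accuracy_all"],
                                      "auc": roc.auc}
        logger.info("stage=eval accuracy=%.1f auc=%.3f",
                    metrics["accuracy_all"], roc.auc)

        # -- netSNP scoring
        bal_rows = np.concatenate([train_rows, val_rows])
        bal_labels = np.concatenate([y_train, y_val])
        order = np.argsort(assoc.fishp, kind="stable")
        targets = assoc.locus_indices[order[:config.n_targets]]
        results = [evaluate_tsnp(store, bal_rows, bal_labels, int(t),
                                 n_reps=config.n_reps, config=config.net,
                                 top_k=config.top_k,
                                 exclude_genes=config.exclude_genes,
                                 seed=derive_seed(config.seed, "tsnp"))
                   for t in targets]
        band = null_band_mcvt(store, bal_rows, bal_labels,
                              n_random=config.n_random, alpha=config.alpha,
                              config=config.net, n_reps=config.null_reps,
                              top_k=config.top_k,
                              exclude_genes=config.exclude_genes,
                              seed=derive_seed(config.seed, "band"))
        classes = classify_tsnps(results, band)
        table = _tsnp_table(store, results, classes, assoc)
        table.to_csv(out / "tsnp.tsv", sep="\t", index=False)
        manifest["stages"]["score"] = {
            "n_protective": len(classes["protective"]),
            "n_risk": len(classes["risk"]),
            "band": [band.lower, band.upper]}
        logger.info("stage=score protective=%d risk=%d",
                    len(classes["protective"]), len(classes["risk"]))

        # -- burden validation
        protective = {r.locus_index: abs(r.mcvt) for r in results
                      if r.locus_index in set(classes["protective"])}
        risk = {r.locus_index: abs(r.mcvt) for r in results
                if r.locus_index in set(classes["risk"])}
        all_rows = _rows_for(store, [r.sample_id for r in records])
        report = burden_mod.validation_report(store, records, all_rows,
                                              protective, risk)
        report.to_csv(out / "validation.tsv", sep="\t", index=False)
        manifest["stages"]["validate"] = {"rows": len(report)}
    except Exception as exc:
        manifest["error"] = {"stage": list(manifest["stages"])[-1] if manifest["stages"] else "load",
                             "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _tsnp_table(store, results, classes, assoc) -> pd.DataFrame:
    fishp_by_locus = dict(zip(assoc.locus_indices.tolist(), assoc.fishp))
    maf_by_locus = dict(zip(assoc.locus_indices.tolist(), assoc.maf))
    cls_of = {}
    for name in ("protective", "risk", "indeterminate"):
        for l in classes[name]:
            cls_of[l] = name
    rows = []
    for r in results:
        locus = store.loci[r.locus_index]
        rows.append({"chr": locus.chromosome, "pos": locus.position,
                     "gene": locus.gene, "mCVt": r.mcvt,
                     "FishP": fishp_by_locus.get(r.locus_index, np.nan),
                     "MAF": maf_by_locus.get(r.locus_index, np.nan),
                     "class": cls_of.get(r.locus_index, "indeterminate"),
                     "p_empirical": classes["p_empirical"][r.locus_index]})
    return pd.DataFrame(rows).sort_values("mCVt").reset_index(drop=True)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
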