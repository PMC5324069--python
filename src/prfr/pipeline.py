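"""End-to-end workflow: simulate/load -> QC -> split -> fit -> evaluate -> annotate.

Driven by a single YAML config with one top-level ``seed``; every
stochastic stage derives its own seed deterministically from it, so a
re-run with the same config reproduces identical outputs (the manifest
records a hash of every artifact to audit exactly that).
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import export_gene_list, map_snps_to_genes, select_top_fraction
from .evaluation import balanced_split, final_model_eval, repeated_cv_performance
from .io import (
    GenotypeMatrix,
    ensure_dir,
    read_gene_bed,
    read_genotypes,
    read_phenotypes,
    sha256_of,
    write_genotypes,
    write_phenotypes,
    align_phenotypes,
)
from .models import MODEL_REGISTRY, oob_permutation_importance
from .qc import QcThresholds, apply_qc
from .simulate import SimConfig, make_gene_fixture, simulate_cohort

log = logging.getLogger("prfr")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed from the run seed (always < 2**31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _load_inputs(cfg: dict, seed: int, outdir: Path):
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", derive_seed(seed, "simulate"))
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        sc = SimConfig(**sim)
        g, v, pheno, truth = simulate_cohort(sc)
        genes, gene_truth = make_gene_fixture(v, n_genes=cfg.get("n_genes", 20),
                                              seed=derive_seed(seed, "genes"))
        write_genotypes(g, v, outdir / "genotypes.tsv", "tsv")
        write_phenotypes(pheno, outdir / "phenotypes.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"causal_snp_ids": truth["causal_snp_ids"],
                       "effects": list(map(float, truth["effects"]))}, fh, indent=1)
        return g, v, pheno, genes
    inp = cfg["input"]
    if not Path(inp["genotypes"]).exists():
        raise FileNotFoundError(f"genotype file not found: {inp['genotypes']}")
    g, v = read_genotypes(inp["genotypes"], inp.get("dialect", "tsv"))
    pheno = read_phenotypes(inp["phenotypes"])
    genes = read_gene_bed(inp["genes"]) if "genes" in inp else None
    return g, v, pheno, genes


def run_pipeline(config, outdir=None) -> dict:
    """Run all stages; returns the manifest (also written as YAML).

    ``config`` is a YAML path or a dict. Stage errors surface with the
    stage name prepended.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    outdir = Path(outdir or cfg.get("outdir", "prfr_run"))
    ensure_dir(outdir)
    manifest = {"config": cfg, "seed": seed, "version": __version__,
                "stages": {}, "warnings": []}

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        st = stage("input")
        g, v, pheno, genes = _load_inputs(cfg, seed, outdir)
        pheno = align_phenotypes(g, pheno)
        st["n_samples"], st["n_snps"] = g.n_samples, g.n_snps

        st = stage("qc")
        qc_cfg = cfg.get("qc", {})
        thresholds = QcThresholds(
            qc_cfg.get("max_missing", 0.05),
            qc_cfg.get("min_maf", 0.05),
            qc_cfg.get("hwe_p", 1e-5),
        )
        g, v, report = apply_qc(g, v, thresholds)
        report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        st.update({k: report.attrs[k] for k in ("n_snps", "n_retained", "n_removed")})

        st = stage("split")
        split_cfg = cfg.get("split", {})
        y = pheno["outcome"].to_numpy()
        split = balanced_split(
            y,
            frac_train=split_cfg.get("frac_train", 2 / 3),
            tolerance=split_cfg.get("tolerance", 0.0),
            seed=derive_seed(seed, "split"),
        )
        st["n_train"] = len(split.train_idx)
        st["n_val"] = len(split.val_idx)
        st["event_rate_train"] = split.event_rate_train
        st["event_rate_val"] = split.event_rate_val
        X = g.to_frame()
        X_tr, X_va = X.iloc[split.train_idx], X.iloc[split.val_idx]
        y_tr, y_va = y[split.train_idx], y[split.val_idx]

        st = stage("fit")
        model_cfg = dict(cfg.get("model", {}))
        kind = model_cfg.pop("kind", "prfr")
        cls = MODEL_REGISTRY[kind]
        model_cfg.setdefault("random_state", derive_seed(seed, "fit"))
        estimator = cls(**model_cfg)
        st["kind"] = kind

        st = stage("evaluate")
        ev = cfg.get("evaluate", {})
        cv = repeated_cv_performance(
            estimator, X_tr, y_tr, X_va, y_va,
            folds=ev.get("folds", 5), repeats=ev.get("repeats", 100),
            seed=derive_seed(seed, "cv"),
        )
        pd.DataFrame({"auc": cv.aucs}).to_csv(outdir / "cv_aucs.tsv",
                                              sep="\t", index=False)
        st["cv_auc_mean"], st["cv_auc_std"] = cv.mean, cv.std
        st["cv_folds_failed"] = cv.n_failed

        final_auc, calib, fitted = final_model_eval(estimator, X_tr, y_tr, X_va, y_va)
        calib.to_csv(outdir / "calibration.tsv", sep="\t", index=False)
        st["final_auc"] = final_auc
        st["calibration_chi2"] = calib.attrs["chi2"]
        st["calibration_p"] = calib.attrs["p"]

        st = stage("importance")
        imp = oob_permutation_importance(
            fitted.model_, X_tr.loc[:, fitted.support_],
            seed=derive_seed(seed, "importance"),
        )
        imp_out = imp.copy()
        imp_out.to_csv(outdir / "importance.tsv", sep="\t", index=False)
        st["n_features"] = len(imp)

        if genes is not None and len(genes):
            st = stage("annotate")
            ann = cfg.get("annotate", {})
            snp_imp = imp[imp["snp_id"].isin(g.snp_ids)]
            sel = select_top_fraction(snp_imp, ann.get("fraction", 0.5))
            hits = map_snps_to_genes(sel, v, genes, ann.get("window_bp", 10_000))
            hits.to_csv(outdir / "gene_hits.tsv", sep="\t", index=False)
            export_gene_list(hits, outdir / "gene_list.txt")
            st["n_selected_snps"] = sel.count
            st["n_genes"] = len(hits)
    except Exception as exc:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    manifest["hashes"] = {
        p.name: sha256_of(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.suffix in (".tsv", ".txt", ".json")
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
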