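"""End-to-end orchestration: normalize -> filter -> SAM -> signature ->
project -> module -> overlap -> survival, driven by one structured config.

Every stage writes its artifact into a run directory with a provenance
header (config hash, seed, package version); a ``summary.json`` collects
the headline numbers. Reruns with the same config and seed produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import compare_activity, project_signature
from .modules import NodeCorrelationModules, overlap_analysis, to_newick
from .prep import (
    collapse_duplicate_genes,
    filter_genes,
    read_expression_matrix,
    write_expression_matrix,
)
from .sam import SAM, Signature
from .survival import km_estimate, logrank_test, rank_split
from .synthdata import KnockdownSimSpec, simulate_knockdown

__all__ = ["RunConfig", "run_pipeline", "reproduce_gse21371"]

# reference values reported for the GSE21371 knockdown signature
GSE21371_REPORTED = {
    "n_called": 2088,
    "n_positive": 892,
    "n_negative": 1196,
    "myb_fold_change": 2.5,
}


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run."""

    matrix: str | None = None           # genes x samples TSV
    labels: str | None = None           # two-column TSV: sample_id, class
    simulate: dict | None = None        # KnockdownSimSpec fields instead of paths
    min_intensity: float = 10.0
    min_present: float = 0.70
    fdr: float = 0.01
    n_perm: int = 1000
    enumeration_limit: int = 10_000
    seed: int = 0
    center: bool = True                 # projection centering
    project_matrix: str | None = None   # optional cohort matrix to project onto
    project_groups: str | None = None   # optional group labels for ANOVA
    module: dict | None = None          # {matrix, seed_gene, min_corr}
    survival: dict | None = None        # {clinical, gene, matrix}

    def validate(self) -> "RunConfig":
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")
        if not 0 < self.min_present <= 1:
            raise ValueError("min_present must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.matrix is None and self.simulate is None:
            raise ValueError("provide either input paths or a simulate block")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw).validate()

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (
        f"# lumisig {__version__} | config {config.hash()} | seed {config.seed}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", **kw)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the configured stages; returns the summary dict (also on disk)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config_hash": config.hash(),
                     "version": __version__}

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        spec = KnockdownSimSpec(**{**config.simulate, "seed": config.seed})
        matrix, labels, truth = simulate_knockdown(spec)
        _write_tsv(truth, outdir / "truth_de.tsv", config, index_label="gene_id")
    else:
        matrix = read_expression_matrix(config.matrix)
        lab = pd.read_csv(config.labels, sep="\t", index_col=0, comment="#")
        labels = lab.iloc[:, 0]
        labels = labels.reindex(matrix.columns)
        if labels.isna().any():
            raise ValueError("labels missing for some samples in the matrix")

    # --- filter + collapse ------------------------------------------------
    matrix = collapse_duplicate_genes(matrix)
    matrix = filter_genes(matrix, min_present=config.min_present)
    write_expression_matrix(matrix, outdir / "filtered_matrix.tsv")
    summary["n_genes_analyzed"] = int(matrix.shape[0])

    # --- SAM --------------------------------------------------------------
    sam = SAM(
        fdr=config.fdr,
        n_perm=config.n_perm,
        enumeration_limit=config.enumeration_limit,
        random_state=config.seed,
    ).fit(matrix, labels)
    res = sam.result_
    per_gene = pd.DataFrame(
        {"d": sam.d_, "r": sam.r_, "s": sam.s_}
    ).rename_axis("gene_id")
    _write_tsv(per_gene, outdir / "sam_genes.tsv", config, float_format="%.6g")
    res.delta_table.to_json(outdir / "delta_table.json", orient="records",
                            double_precision=10)
    signature = sam.signature_
    _write_tsv(signature.to_frame(), outdir / "signature.tsv", config,
               float_format="%.6g")
    summary["sam"] = {
        "s0": res.s0,
        "n_permutations": res.n_permutations,
        "exhaustive": res.exhaustive,
        "fdr_threshold": config.fdr,
        "signature_size": len(signature),
        "n_positive": len(signature.positive_set),
        "n_negative": len(signature.negative_set),
    }

    # --- projection -------------------------------------------------------
    if config.project_matrix and len(signature):
        target = read_expression_matrix(config.project_matrix)
        act = project_signature(signature, target, center=config.center,
                                name="sam_signature")
        _write_tsv(act.scores.to_frame(), outdir / "activity.tsv", config,
                   index_label="sample_id", float_format="%.6g")
        summary["projection"] = {"n_genes_matched": act.n_genes_matched}
        if config.project_groups:
            grp = pd.read_csv(config.project_groups, sep="\t", index_col=0,
                              comment="#").iloc[:, 0]
            cmp = compare_activity(act.scores, grp.reindex(act.scores.index))
            summary["projection"]["anova_F"] = cmp["F"]
            summary["projection"]["anova_p"] = cmp["p"]

    # --- module + overlap -------------------------------------------------
    if config.module:
        mod_cfg = dict(config.module)
        mod_matrix = (
            read_expression_matrix(mod_cfg["matrix"])
            if "matrix" in mod_cfg
            else matrix
        )
        est = NodeCorrelationModules(
            min_corr=float(mod_cfg.get("min_corr", 0.65))
        ).fit(mod_matrix)
        module = est.extract(mod_cfg["seed_gene"])
        (outdir / "dendrogram.nwk").write_text(to_newick(est.tree_) + "\n")
        _write_tsv(pd.DataFrame({"gene_id": module}), outdir / "module.tsv",
                   config, index=False)
        summary["module"] = {"size": len(module),
                             "seed_gene": mod_cfg["seed_gene"]}
        if len(signature):
            rep = overlap_analysis(module, {"sam_signature": signature.gene_ids})
            summary["module"]["overlap_pct"] = rep.percentages

    # --- survival ---------------------------------------------------------
    if config.survival:
        s_cfg = dict(config.survival)
        s_matrix = (
            read_expression_matrix(s_cfg["matrix"])
            if "matrix" in s_cfg
            else matrix
        )
        clinical = pd.read_csv(s_cfg["clinical"], sep="\t", index_col=0,
                               comment="#")
        gene = s_cfg["gene"]
        expr = s_matrix.loc[gene, clinical.index]
        split = rank_split(expr)
        lr = logrank_test(
            clinical["os_time"], clinical["os_event"].astype(bool), split
        )
        curves = km_estimate(
            clinical["os_time"], clinical["os_event"].astype(bool), split
        )
        km_rows = [
            {"group": c.group, "time": t, "survival": s, "at_risk": r}
            for c in curves.values()
            for t, s, r in zip(c.times, c.survival, c.at_risk)
        ]
        _write_tsv(pd.DataFrame(km_rows), outdir / "km_curves.tsv", config,
                   index=False, float_format="%.6g")
        summary["survival"] = {"gene": gene, **lr}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def reproduce_gse21371(download_dir) -> dict | None:
    """Re-derive the GSE21371 knockdown signature from user-supplied files.

    Expects ``matrix.tsv`` (genes x samples log2 ratios, 5 shMYB + 6
    shGFP arrays) and ``labels.tsv`` (sample_id, class) prepared from the
    GEO series in ``download_dir``. Runs the presence filter and a
    two-class SAM at FDR < 1% and reports the called/positive/negative
    counts and the MYB knockdown fold change side by side with the
    reference values reported for this experiment
    (2,088 genes; 892 positive; 1,196 negative; 2.5-fold decrease).

    Returns None (with a notice) when the files are absent; this path is
    network-dependent and never part of the default analysis.
    """
    d = Path(download_dir)
    matrix_path, labels_path = d / "matrix.tsv", d / "labels.tsv"
    if not matrix_path.exists() or not labels_path.exists():
        print(
            f"GSE21371 files not found under {d}; skipping reproduction "
            "(expected matrix.tsv and labels.tsv)."
        )
        return None
    matrix = collapse_duplicate_genes(read_expression_matrix(matrix_path))
    labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    labels = labels.reindex(matrix.columns)
    matrix = filter_genes(matrix, min_present=0.70)
    sam = SAM(fdr=0.01).fit(matrix, labels)
    sig = sam.signature_
    report = {
        "n_called": len(sig),
        "n_positive": len(sig.positive_set),
        "n_negative": len(sig.negative_set),
        "reported": GSE21371_REPORTED,
    }
    if "MYB" in matrix.index:
        is_kd = labels.to_numpy() == labels.iloc[0]
        contrast = (
            matrix.loc["MYB"][~is_kd].mean() - matrix.loc["MYB"][is_kd].mean()
        )
        report["myb_fold_change"] = float(2.0 ** abs(contrast))
    return report
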