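"""End-to-end orchestration: simulate -> catalog -> tree -> express -> integrate -> rank.

A single JSON-serialisable :class:`PipelineConfig` drives every stage; all
randomness flows from one seed through named per-stage substreams, and no
output file embeds timestamps, so a config + seed reproduces the bundle
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, catalog, cca, expression, phylo, simulate

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("ccanet")

STAGES = ("simulate", "catalog", "tree", "express", "integrate", "rank")


@dataclass
class PipelineConfig:
    """Stage toggles, thresholds and data sources for one reproducible run.

    Exactly one of (simulate=True) or explicit input paths must provide each
    consumed data stream.  Thresholds carry the pipeline defaults: homology
    filters (evalue 1e-5, bitscore 100, length 100), duplicate identity 95%,
    network cutoff 0.5, Tukey alpha 0.01, bootstrap 1000.
    """

    outdir: str = "ccanet_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulate: bool = True
    # explicit inputs (used when simulate is False)
    expression_path: str | None = None
    metabolite_path: str | None = None
    fasta_path: str | None = None
    domains_path: str | None = None
    hits_path: str | None = None
    alignment_path: str | None = None
    # thresholds
    max_evalue: float = 1e-5
    min_bitscore: float = 100.0
    min_aln_length: int = 100
    min_identity_pct: float = 95.0
    cutoff: float = 0.5
    score_method: str = "direct_pearson"
    ridge: float = 0.0
    min_fold: float = 1.0
    alpha: float = 0.01
    bootstrap_reps: int = 100
    n_replicates: int = 3
    noise_cv: float = 0.2
    n_tfs: int = 112
    target_rho1: float = 0.968

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if not self.stages:
            raise ValueError("no stages enabled")
        needs_data = {"catalog", "express", "integrate"} & set(self.stages)
        if not self.simulate and needs_data:
            paired = {
                "catalog": (self.fasta_path, self.domains_path),
                "express": (self.expression_path,),
                "integrate": (self.expression_path, self.metabolite_path),
            }
            for stage in sorted(needs_data):
                if any(p is None for p in paired[stage]):
                    raise ValueError(
                        f"stage {stage!r} needs input paths when simulate is off"
                    )
        if self.simulate and any(
            p is not None
            for p in (self.expression_path, self.metabolite_path, self.fasta_path)
        ):
            raise ValueError("give either simulate=True or input paths, not both")
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.score_method not in cca.SCORE_METHODS:
            raise ValueError(f"unknown score method {self.score_method!r}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        cfg["stages"] = list(cfg["stages"])
        cfg.pop("outdir")  # the bundle's location is not part of its identity
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
            "ccanet_version": __version__,
        }


def _substream_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGES, ss.spawn(len(STAGES)))
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the enabled stages in dependency order; return written paths.

    Logs per-stage record counts to the ``ccanet`` logger; raises on any
    stage error (the CLI converts that to a nonzero exit).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _substream_seeds(config.seed)
    written: dict[str, Path] = {}
    enabled = set(config.stages)

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> Path:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        written[name] = path
        return path

    # --- data layer -------------------------------------------------------
    expr = metab = seqs = domains = hits = truth = None
    if "simulate" in enabled and config.simulate:
        ind = simulate.default_induction_config(
            n_replicates=config.n_replicates,
            noise_cv=config.noise_cv,
            seed=seeds["simulate"],
            n_tfs=config.n_tfs,
        )
        expr = simulate.gen_timecourse_expression(ind)
        coupled = simulate.gen_coupled_metabolites(
            expr, simulate.default_coupling_spec(config.target_rho1, seed=seeds["simulate"])
        )
        metab, truth = coupled.values, coupled.truth
        seqs, domains, hits = simulate.gen_protein_set(
            simulate.ProteinSetSpec(seed=seeds["simulate"])
        )
        emit("expression", expr.rename_axis("gene_id"), index=True)
        emit("metabolites", metab.rename_axis("metabolite_id"), index=True)
        log.info("simulate: %d genes x %d samples, %d metabolites", *expr.shape, len(metab))
    else:
        if config.expression_path:
            expr = pd.read_csv(config.expression_path, sep="\t", index_col=0)
        if config.metabolite_path:
            metab = pd.read_csv(config.metabolite_path, sep="\t", index_col=0)
        if config.fasta_path:
            seqs = catalog.read_fasta(config.fasta_path)
        if config.domains_path:
            domains = catalog.read_domain_table(config.domains_path)
        if config.hits_path:
            hits = catalog.read_hit_table(config.hits_path)

    # --- catalogue --------------------------------------------------------
    labels = None
    if "catalog" in enabled and seqs is not None and domains is not None:
        table = catalog.catalog_table(seqs, domains, hits=hits)
        emit("catalog", table)
        labels = table.set_index("protein_id")["family"]
        dupes = catalog.detect_duplicates(seqs, min_identity_pct=config.min_identity_pct)
        emit(
            "duplicates",
            pd.DataFrame(
                [(p.id1, p.id2, p.identity_pct) for p in dupes],
                columns=["ID1", "ID2", "Identity (%)"],
            ),
        )
        summary = catalog.summarize_duplicates(dupes)
        log.info(
            "catalog: %d proteins, %d duplicate pairs over %d genes",
            len(table), summary.n_pairs, summary.n_distinct_genes,
        )

    # --- phylogeny --------------------------------------------------------
    if "tree" in enabled:
        aln = None
        if config.alignment_path:
            aln = phylo.read_aligned_fasta(config.alignment_path)
        elif seqs is not None and domains is not None:
            # align-free shortcut for simulated data: the planted AP2 domains
            # are generated ungapped at equal length, so they stack directly
            rows, ids = [], []
            ap2 = domains[domains["domain_type"] == "AP2"].drop_duplicates("protein_id")
            for row in ap2.itertuples(index=False):
                ids.append(row.protein_id)
                rows.append(seqs[row.protein_id][row.start - 1 : row.end])
            if len(ids) >= 4 and len({len(r) for r in rows}) == 1:
                aln = phylo.Alignment(tuple(ids), tuple(rows))
        if aln is not None:
            supported = phylo.bootstrap_support(
                aln, n_reps=config.bootstrap_reps, seed=seeds["tree"]
            )
            path = outdir / "tree.nwk"
            path.write_text(supported.newick() + "\n")
            written["tree"] = path
            log.info("tree: %d taxa, %d bootstrap reps", len(aln.ids), config.bootstrap_reps)

    # --- expression profiling --------------------------------------------
    fc = None
    if "express" in enabled and expr is not None:
        fc = expression.fold_change(expr)
        emit("fold_change", fc.fold.rename_axis("gene_id"), index=True)
        emit("ln_fold_change", fc.ln_fold.rename_axis("gene_id"), index=True)
        calls = expression.classify_regulation(fc, min_fold=config.min_fold)
        emit("regulation_calls", calls.rename_axis("gene_id").to_frame(), index=True)
        log.info("express: %s", calls.value_counts().to_dict())

    # --- integration ------------------------------------------------------
    nets: dict[str, cca.BipartiteNetwork] = {}
    if "integrate" in enabled and expr is not None and metab is not None:
        gene_ln = np.log(expr.dropna())
        Y = metab.T
        pathway = [g for g in gene_ln.index if g in simulate.PATHWAY_GENE_FOLDS]
        blocks = {"gene": pathway or list(gene_ln.index)[:8]}
        if labels is not None:
            tf_ids = [g for g in gene_ln.index if g not in blocks["gene"]]
            if tf_ids:
                blocks["tf"] = tf_ids
        # CCA on the pathway-gene block
        Xg = gene_ln.loc[blocks["gene"]].T
        fit = cca.cca_fit(Xg, Y, ridge=config.ridge if config.ridge else 0.0)
        pd.DataFrame({"rho": fit.rho}).to_csv(outdir / "cca_rho.tsv", sep="\t", index=False)
        written["cca_rho"] = outdir / "cca_rho.tsv"
        emit("cca_loadings", cca.variable_loadings(fit, Xg, Y))
        scores = cca.association_scores(Xg, Y, method=config.score_method, ridge=config.ridge)
        emit("gene_metabolite_scores", scores.scores.rename_axis("gene_id"), index=True)
        net = cca.build_network(scores, cutoff=config.cutoff)
        emit("gene_metabolite_network", net.to_edge_frame())
        net.write_graphml(outdir / "gene_metabolite_network.graphml")
        nets["gene_metabolite"] = net
        log.info("integrate: rho1=%.3f, %d edges", fit.rho[0], len(net.edges))
        if "tf" in blocks:
            Xt = gene_ln.loc[blocks["tf"]].T
            tf_met = cca.association_scores(Xt, Y, method=config.score_method)
            tf_gene = cca.association_scores(Xt, Xg, method=config.score_method)
            nets["tf_metabolite"] = cca.build_network(tf_met, cutoff=config.cutoff)
            nets["tf_gene"] = cca.build_network(tf_gene, cutoff=config.cutoff)
            emit("tf_metabolite_network", nets["tf_metabolite"].to_edge_frame())
            emit("tf_gene_network", nets["tf_gene"].to_edge_frame())

    # --- regulator nomination --------------------------------------------
    if "rank" in enabled and {"tf_metabolite", "tf_gene"} <= set(nets):
        fam = labels.to_dict() if labels is not None else {}
        tf_nodes = set(nets["tf_metabolite"].left_nodes) | set(nets["tf_gene"].left_nodes)
        for t in tf_nodes:
            fam.setdefault(t, "unclassified")
        report = cca.rank_regulators(nets["tf_metabolite"], nets["tf_gene"], fam)
        path = outdir / "common_tfs.json"
        path.write_text(
            json.dumps(
                {
                    "metabolite_correlated": {k: list(v) for k, v in report.metabolite_correlated.items()},
                    "gene_correlated": {k: list(v) for k, v in report.gene_correlated.items()},
                    "common": {k: list(v) for k, v in report.common.items()},
                    "common_union": list(report.common_union),
                    "top_per_entity": {k: list(v) for k, v in report.top_per_entity.items()},
                },
                indent=1,
                sort_keys=True,
            )
        )
        written["common_tfs"] = path
        log.info("rank: %d common TFs", len(report.common_union))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(config.manifest(), indent=1, sort_keys=True))
    written["manifest"] = manifest_path
    return written
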