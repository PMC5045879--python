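"""End-to-end orchestration: normalize -> DEG -> GGM -> topology -> communities -> drug query.

A :class:`PipelineConfig` (YAML round-trippable) names the inputs, output
directory and all stage parameters.  Each stage writes its artifact together
with a manifest recording input hashes and parameters; a re-run with
matching hashes reuses the cached artifact, so repeated runs are idempotent
and the run report is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from stressnet import communities as comm
from stressnet import connectivity as conn
from stressnet import deg as degmod
from stressnet import ggm as ggmmod
from stressnet import io as iomod
from stressnet import synthetic
from stressnet import topology as topo

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, outputs and stage parameters of one pipeline run."""

    expression: str
    out_dir: str
    reference: str | None = None  # rank-matrix signature reference (optional stage)
    gene_sets: str | None = None  # GMT for community over-representation (optional)
    # DEG stage
    deg_alpha: float = 0.01
    query_alpha: float = 0.05
    use_adjusted: bool = False
    min_run: int = 2
    direction: str = "baseline"
    # GGM stage
    ggm_mode: str = "top_fraction"
    ggm_q: float = 0.01
    ggm_alpha: float = 0.01
    # topology stage
    sv_thresholds: tuple[float, ...] = (0.10, 0.15, 0.20)
    # communities stage
    k_min: int = 3
    k_max: int = 6
    cluster_min_size: int = 3
    cluster_penalty: float = 2.0
    # connectivity stage
    n_perm: int = 100_000
    perm_alpha: float = 0.05
    perm_adjust: str = "bh"  # BH across drugs; "none" for the raw permutation p
    seed: int = 1

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sv_thresholds"] = list(self.sv_thresholds)
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "sv_thresholds" in data:
            data["sv_thresholds"] = tuple(data["sv_thresholds"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_key(inputs: list[Path], params: dict) -> str:
    h = hashlib.sha256()
    for p in inputs:
        h.update(_sha256(p).encode())
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _cached(manifest_path: Path, key: str, artifacts: list[Path]) -> bool:
    if not manifest_path.exists():
        return False
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return False
    return manifest.get("key") == key and manifest.get("complete") and all(
        a.exists() for a in artifacts
    )


def _write_manifest(manifest_path: Path, key: str, params: dict, complete: bool) -> None:
    manifest_path.write_text(
        json.dumps({"key": key, "params": params, "complete": complete}, sort_keys=True, default=str)
        + "\n"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order and return the run report."""
    expr_path = Path(config.expression)
    if not expr_path.exists():
        raise FileNotFoundError(f"expression input not found: {expr_path}")
    for opt in (config.reference, config.gene_sets):
        if opt is not None and not Path(opt).exists():
            raise FileNotFoundError(f"input not found: {opt}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    # --- stage 1-2: normalization + DEG calling -------------------------------
    deg_params = {
        "deg_alpha": config.deg_alpha,
        "query_alpha": config.query_alpha,
        "use_adjusted": config.use_adjusted,
        "min_run": config.min_run,
        "direction": config.direction,
    }
    series = iomod.read_expression_table(expr_path)
    normalized = degmod.quantile_normalize(series)
    fit = degmod.fit_contrasts(normalized)
    mstats = degmod.moderate(fit)
    degs = degmod.select_degs(
        mstats, config.deg_alpha, use_adjusted=config.use_adjusted, direction=config.direction
    )
    query_degs = degmod.select_degs(
        mstats, config.query_alpha, use_adjusted=config.use_adjusted, direction=config.direction
    )
    up_set, down_set = degmod.consecutive_direction_filter(query_degs, min_run=config.min_run)
    key = _stage_key([expr_path], deg_params)
    deg_table_path = out / "degs.tsv"
    frame = mstats.as_frame().loc[degs.genes]
    frame.to_csv(deg_table_path, sep="\t")
    iomod.write_gene_set(up_set, out / "up.grp")
    iomod.write_gene_set(down_set, out / "down.grp")
    _write_manifest(out / "deg.manifest.json", key, deg_params, True)
    logger.info("moderation prior: d0=%.3g, s0^2=%.4g", mstats.d0, mstats.s02)
    report["d0"] = mstats.d0
    report["s0_squared"] = mstats.s02
    report["n_degs"] = len(degs)
    report["n_up_query"] = len(up_set)
    report["n_down_query"] = len(down_set)
    report["stages"].append("deg")

    # --- stage 3: GGM network over the DEGs ----------------------------------
    gan_path = out / "gan.tsv"
    if len(degs) >= 5:
        deg_expr = normalized.subset(degs.genes)
        samples = deg_expr.matrix().T  # observations (all columns) × genes
        network = ggmmod.build_pcor_network(samples, degs.genes)
        gan = ggmmod.select_edges(
            network, mode=config.ggm_mode, q=config.ggm_q, alpha=config.ggm_alpha
        )
        iomod.write_network(gan, gan_path, dialect="tsv")
        iomod.write_network(gan, out / "gan.sif", dialect="sif")
        report["shrinkage_lambda"] = network.shrinkage
        report["n_gan_nodes"] = gan.number_of_nodes()
        report["n_gan_edges"] = gan.number_of_edges()
        report["stages"].append("ggm")
    else:
        gan = None
        logger.warning("too few DEGs (%d) for GGM inference; network stages skipped", len(degs))

    # --- stage 4: topology + SV scores ---------------------------------------
    if gan is not None and gan.number_of_nodes() >= 2:
        profile = topo.local_parameters(gan)
        avg_d, diam, eff = topo.global_parameters(gan)
        profile = topo.TopologyProfile(
            raw=profile.raw, average_distance=avg_d, diameter=diam, efficiency=eff
        )
        profile = topo.normalize_profile(profile)
        scorecard = topo.sv_scores(profile, thresholds=tuple(config.sv_thresholds))
        sv_table = topo.sv_rank_table(scorecard)
        profile.raw.to_csv(out / "topology_raw.tsv", sep="\t")
        assert profile.normalized is not None
        profile.normalized.to_csv(out / "topology_normalized.tsv", sep="\t")
        sv_table.to_csv(out / "sv_counts.tsv", sep="\t")
        scorecard.sv.to_csv(out / "sv_scores.tsv", sep="\t")
        report["average_distance"] = avg_d
        report["diameter"] = diam
        report["efficiency"] = eff
        report["mean_degree_centrality"] = float(profile.raw["DC"].mean())
        report["sv_counts"] = {
            str(idx): {str(col): int(v) for col, v in row.items()}
            for idx, row in sv_table.iterrows()
        }
        report["stages"].append("topology")

        # --- stage 5: communities --------------------------------------------
        community_sets = []
        for k in range(config.k_min, config.k_max + 1):
            community_sets.append(comm.k_clique_communities(gan, k))
        size_table = comm.community_size_table(community_sets)
        size_table.to_csv(out / "communities.tsv", sep="\t")
        clusters = comm.cohesiveness_clusters(
            gan, min_size=config.cluster_min_size, penalty=config.cluster_penalty
        )
        report["community_sizes"] = {int(cs.k): cs.sizes() for cs in community_sets}  # type: ignore[arg-type]
        report["n_cohesive_clusters"] = len(clusters)
        report["stages"].append("communities")

        if config.gene_sets is not None and community_sets[0].communities:
            sets = iomod.read_gene_sets(config.gene_sets)
            universe = set(series.gene_ids)
            ora = comm.over_representation(community_sets[0].largest(), sets, universe)
            ora.to_csv(out / "ora.tsv", sep="\t")
            report["stages"].append("ora")

    # --- stage 6: connectivity query -----------------------------------------
    if config.reference is not None and up_set and down_set:
        reference = iomod.read_signature_reference(config.reference)
        uni = set(reference.universe)
        up_q = frozenset(up_set & uni)
        down_q = frozenset(down_set & uni)
        if up_q and down_q:
            conn_params = {
                "n_perm": config.n_perm,
                "seed": config.seed,
                "alpha": config.perm_alpha,
                "adjust": config.perm_adjust,
                "up": sorted(up_q),
                "down": sorted(down_q),
            }
            conn_key = _stage_key([Path(config.reference)], conn_params)
            drug_path = out / "drug_scores.tsv"
            conn_manifest = out / "connectivity.manifest.json"
            if _cached(conn_manifest, conn_key, [drug_path]):
                logger.info("connectivity stage cache hit; reusing %s", drug_path)
                drugs = _read_drug_table(drug_path)
            else:
                query = conn.QuerySignature(up_q, down_q)
                result = conn.run_query(
                    query,
                    reference,
                    drug_groups=synthetic.instance_drug_groups(reference.perturbations),
                    n_perm=config.n_perm,
                    seed=config.seed,
                    alpha=config.perm_alpha,
                    adjust=config.perm_adjust,
                )
                drugs = result.drugs
                drugs.to_csv(drug_path, sep="\t")
                _write_manifest(conn_manifest, conn_key, conn_params, True)
            candidates = list(
                conn.repositioning_candidates(drugs, alpha=config.perm_alpha).index
            )
            iomod.write_gene_set(candidates, out / "candidates.grp")
            report["n_candidate_drugs"] = len(candidates)
            report["candidates"] = candidates
            report["stages"].append("connectivity")
        else:
            logger.warning("query sets empty after restriction to the reference universe")

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report


# ---------------------------------------------------------------------------
# fixture bundles


def _read_drug_table(path: Path):
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    df["candidate"] = df["candidate"].astype(bool)
    return df


def make_fixtures(seed: int, scale: str = "small", out_dir: str | Path = "fixtures") -> dict:
    """Write a complete synthetic input bundle (expression, truth, sets, reference).

    ``small`` (default) is sized for fast CI runs; ``paper-like`` matches the
    study design scale (>= 10,000 genes, 4 time points × 2 replicates).
    """
    if scale == "small":
        n_genes, n_drugs, n_rev, n_inst = 400, 50, 5, 3
    elif scale == "paper-like":
        n_genes, n_drugs, n_rev, n_inst = 10_000, 200, 10, 3
    else:
        raise ValueError(f"unknown scale {scale!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    series, truth = generate_bundle_timecourse(n_genes, int(ss[0]))
    iomod.write_expression_table(series, out / "expression.tsv")
    _write_truth(truth, out / "truth.tsv")
    # gene sets: planted DEGs and random sets, for over-representation tests
    rng = np.random.default_rng(int(ss[1]))
    genes = series.gene_ids
    with (out / "sets.gmt").open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("planted_degs\tplanted differential genes\t" + "\t".join(sorted(truth.deg_genes())) + "\n")
        for i in range(5):
            members = rng.choice(genes, size=25, replace=False)
            fh.write(f"random_{i}\trandom control set\t" + "\t".join(sorted(members)) + "\n")
    # signature reference reversing the planted up/down signature
    up = frozenset(g for g, lab in truth.deg_labels.items() if lab == "up")  # type: ignore[union-attr]
    down = frozenset(g for g, lab in truth.deg_labels.items() if lab == "down")  # type: ignore[union-attr]
    query = conn.QuerySignature(up, down)
    reference, ref_truth = synthetic.generate_signature_reference(
        genes, n_drugs, query, n_rev, noise=0.02, seed=int(ss[2]), instances_per_drug=n_inst
    )
    iomod.write_signature_reference(reference, out / "reference.tsv")
    (out / "reversers.txt").write_text("\n".join(sorted(ref_truth.reverser_drugs)) + "\n")
    config = PipelineConfig(
        expression=str(out / "expression.tsv"),
        reference=str(out / "reference.tsv"),
        gene_sets=str(out / "sets.gmt"),
        out_dir=str(out / "results"),
        n_perm=2000 if scale == "small" else 100_000,
        seed=seed,
    )
    config.to_yaml(out / "run.yaml")
    return {
        "expression": str(out / "expression.tsv"),
        "reference": str(out / "reference.tsv"),
        "gene_sets": str(out / "sets.gmt"),
        "config": str(out / "run.yaml"),
        "n_genes": n_genes,
        "reversers": sorted(ref_truth.reverser_drugs),
    }


def generate_bundle_timecourse(n_genes: int, seed: int):
    return synthetic.generate_timecourse(
        n_genes=n_genes,
        deg_fraction=0.05,
        effect_size=2.0,
        noise_sd=0.3,
        seed=seed,
    )


def _write_truth(truth, path: Path) -> None:
    assert truth.deg_labels is not None and truth.effects is not None
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        cols = list(truth.effects.columns)
        fh.write("gene\tlabel\t" + "\t".join(f"effect_{c}" for c in cols) + "\n")
        for gene, label in truth.deg_labels.items():
            eff = truth.effects.loc[gene]
            fh.write(gene + "\t" + label + "\t" + "\t".join(repr(float(v)) for v in eff) + "\n")
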