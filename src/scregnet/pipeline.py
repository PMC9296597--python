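"""End-to-end pipeline orchestration with a provenance manifest.

Stages run in dependency order: simulate (or load) -> qc -> features ->
deviations -> tumor_tfs -> cre -> nmf -> lr -> drugs. Each stage derives its
seed deterministically from the global seed (seed + stage index), writes its
outputs once into the run directory, and records their SHA-256 hashes in the
manifest, so identical configs and seeds yield byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import numpy as np
import pandas as pd
import yaml

from . import cre, deviation, features, interactions, io, nmf, qc, tumor_tf
from ._utils import detection_fraction_frame, normalize_log1p
from .synthetic import SyntheticConfig, generate_drug_zscores, generate_multiome

STAGES = ["simulate", "qc", "features", "deviations", "tumor_tfs", "cre",
          "nmf", "lr", "drugs"]

DEFAULT_PARAMS: dict[str, dict] = {
    "qc": {},
    "features": {"min_log2fc": 0.25, "alpha": 0.05},
    "deviations": {"n_iter": 50, "k": 50, "score": "z"},
    "tumor_tfs": {"fc_in": 4.0, "fc_out_max": 1.0, "alpha": 1e-4,
                  "mad_multiplier": 4.0},
    "cre": {"group_size": 10, "window": 500_000, "coaccess_cutoff": 0.2,
            "base_penalty": 0.2, "q_cut": 0.05, "min_detection": 0.05},
    "nmf": {"k_min": 2, "k_max": 6, "nrun": 30, "top_n": 30,
            "min_coverage_fraction": 0.5},
    "lr": {"min_frac": 0.1, "n_perm": 1000, "p_cut": 0.05, "mean_cut": 1.0,
           "n_background_pairs": 24},
    "drugs": {"n_drugs": 60, "n_genes": 120, "z_cut": -2.0},
}


@dataclasses.dataclass
class PipelineConfig:
    """Synthetic-generation parameters plus per-stage parameter blocks."""

    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    inputs: dict | None = None  # optional on-disk inputs instead of simulation
    params: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        self.synthetic.validate()
        for stage, block in self.params.items():
            if stage not in DEFAULT_PARAMS:
                raise ValueError(f"unknown stage {stage!r} in params")
            unknown = set(block) - set(DEFAULT_PARAMS[stage])
            if unknown:
                raise ValueError(f"unknown parameter(s) {sorted(unknown)} "
                                 f"for stage {stage!r}")
        if self.inputs is not None:
            required = ["rna_prefix", "atac_prefix", "peaks_bed",
                        "motifs_prefix", "genes_tsv", "cells_tsv"]
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ValueError(f"inputs block missing keys: {missing}")
            for key in required:
                path = self.inputs[key]
                probe = path if key in ("peaks_bed", "genes_tsv", "cells_tsv") \
                    else path + ".mtx"
                if not os.path.exists(probe):
                    raise FileNotFoundError(f"input {key!r}: {probe}")

    def stage_params(self, stage: str) -> dict:
        merged = dict(DEFAULT_PARAMS.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.get("synthetic") or {}).items()})
        return cls(synthetic=syn, inputs=raw.get("inputs"),
                   params=raw.get("params") or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str, seed: int = 0,
                 stop_after: str | None = None) -> dict:
    """Run the pipeline, write all outputs under ``outdir``, return the manifest.

    ``stop_after`` truncates the stage list (stages are a linear chain).
    Raises with the failing stage named; outputs of completed stages remain.
    """
    config.validate()
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    os.makedirs(outdir, exist_ok=True)
    stages = STAGES[:STAGES.index(stop_after) + 1] if stop_after else STAGES
    stage_seed = {s: seed + i for i, s in enumerate(STAGES)}
    from . import __version__
    manifest: dict = {
        "package": "scregnet", "version": __version__, "seed": seed,
        "stages": stages, "stage_seeds": stage_seed,
        "config": config.to_dict(), "outputs": {},
    }
    state: dict = {}

    def emit(stage: str, name: str, writer) -> None:
        path = os.path.join(outdir, name)
        writer(path)
        manifest["outputs"].setdefault(stage, {})[name] = _sha256(path)

    def emit_counts(stage: str, name: str, adata) -> None:
        prefix = os.path.join(outdir, name)
        io.write_counts(prefix, adata)
        for suffix in (".mtx", ".barcodes.tsv", ".features.tsv"):
            manifest["outputs"].setdefault(stage, {})[name + suffix] = \
                _sha256(prefix + suffix)

    def emit_existing(stage: str, name: str) -> None:
        manifest["outputs"].setdefault(stage, {})[name] = \
            _sha256(os.path.join(outdir, name))

    emit.counts = emit_counts  # type: ignore[attr-defined]
    emit.existing = emit_existing  # type: ignore[attr-defined]

    for stage in stages:
        try:
            _run_stage(stage, config, state, stage_seed[stage], outdir, emit)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _run_stage(stage, config, state, sseed, outdir, emit):
    if stage == "simulate":
        if config.inputs is None:
            syn = dataclasses.replace(config.synthetic, seed=config.synthetic.seed + sseed)
            rna, atac, peaks, motifs, genes, cells, truth = generate_multiome(syn)
        else:
            rna = io.read_counts(config.inputs["rna_prefix"])
            atac = io.read_counts(config.inputs["atac_prefix"])
            peaks = io.read_peaks(config.inputs["peaks_bed"])
            motifs = io.read_motif_hits(config.inputs["motifs_prefix"])
            genes = pd.read_csv(config.inputs["genes_tsv"], sep="\t", index_col=0)
            cells = pd.read_csv(config.inputs["cells_tsv"], sep="\t", index_col=0)
            truth = (io.read_truth(config.inputs["truth_json"])
                     if config.inputs.get("truth_json") else None)
            rna.obs = cells.loc[rna.obs_names, ["sample", "cell_type"]].copy()
            atac.obs = cells.loc[atac.obs_names, ["sample", "cell_type"]].copy()
        state.update(rna=rna, atac=atac, peaks=peaks, motifs=motifs,
                     genes=genes, cells=cells, truth=truth)
        emit.counts(stage, "rna", state["rna"])
        emit.counts(stage, "atac", state["atac"])
        emit(stage, "peaks.bed", lambda p: io.write_peaks(p, peaks))
        emit.existing(stage, "peaks.bed.gc.tsv")  # sidecar of write_peaks
        io.write_motif_hits(os.path.join(outdir, "motif_hits"), motifs)
        for suffix in (".mtx", ".peaks.tsv", ".motifs.tsv"):
            emit.existing(stage, "motif_hits" + suffix)
        emit(stage, "genes.tsv", lambda p: genes.to_csv(p, sep="\t"))
        emit(stage, "cells.tsv", lambda p: cells.to_csv(p, sep="\t"))
        if truth is not None:
            emit(stage, "truth.json", lambda p: io.write_truth(p, truth))

    elif stage == "qc":
        cells = state["cells"]
        rna_audit = qc.rna_qc_audit(cells.reset_index().rename(
            columns={"index": "cell_id"})[["cell_id", "n_genes", "n_umi",
                                           "mito_fraction"]])
        atac_audit = qc.atac_qc_audit(cells.reset_index()[[
            "cell_id", "peak_region_fragments", "frip", "blacklist_ratio",
            "nucleosome_signal", "tss_enrichment"]])
        kept = list(rna_audit.index[(rna_audit.kept & atac_audit.kept)])
        state["kept_cells"] = kept
        state["rna_f"] = state["rna"][kept].copy()
        state["atac_f"] = state["atac"][kept].copy()
        labels = state["cells"].loc[kept, "cell_type"]
        jac = qc.jaccard_index(labels.to_dict(), labels.to_dict())
        emit(stage, "rna_qc_audit.tsv", lambda p: rna_audit.to_csv(p, sep="\t"))
        emit(stage, "atac_qc_audit.tsv", lambda p: atac_audit.to_csv(p, sep="\t"))
        emit(stage, "kept_cells.txt",
             lambda p: pd.Series(kept).to_csv(p, index=False, header=False))
        emit(stage, "annotation_jaccard.tsv", lambda p: jac.to_csv(p, sep="\t"))

    elif stage == "features":
        pars = config.stage_params("features")
        rna_f, atac_f = state["rna_f"], state["atac_f"]
        labels = rna_f.obs.cell_type
        activity = features.gene_activity_scores(atac_f, state["peaks"],
                                                 state["genes"])
        categories = features.annotate_peaks(state["peaks"], state["genes"])
        degs = features.find_differential_features(
            rna_f.X, rna_f.var_names, labels, **pars)
        dars = features.find_differential_features(
            atac_f.X, atac_f.var_names, labels, **pars)
        state.update(activity=activity, peak_categories=categories,
                     degs=degs, dars=dars)
        emit.counts(stage, "gene_activity", activity)
        emit(stage, "peak_categories.tsv", lambda p: categories.to_csv(p, sep="\t"))
        emit(stage, "degs.tsv", lambda p: degs.to_csv(p, sep="\t", index=False))
        emit(stage, "dars.tsv", lambda p: dars.to_csv(p, sep="\t", index=False))

    elif stage == "deviations":
        pars = config.stage_params("deviations")
        atac_f = state["atac_f"]
        backgrounds = deviation.sample_background_peaks(
            state["peaks"], atac_f, n_iter=pars["n_iter"], k=pars["k"],
            seed=sseed)
        dev = deviation.compute_deviations(atac_f, state["motifs"], backgrounds)
        diff = deviation.differential_tf_activity(
            dev, atac_f.obs.cell_type, score=pars["score"])
        state.update(dev=dev, tf_diff=diff)
        emit(stage, "deviations.tsv", lambda p: dev.deviations.to_csv(p, sep="\t"))
        emit(stage, "deviation_z.tsv", lambda p: dev.z.to_csv(p, sep="\t"))
        emit(stage, "tf_differential.tsv",
             lambda p: diff.to_csv(p, sep="\t", index=False))

    elif stage == "tumor_tfs":
        pars = config.stage_params("tumor_tfs")
        variab = tumor_tf.tf_variability(state["dev"],
                                         state["atac_f"].obs.cell_type)
        selected, table = tumor_tf.select_specific_tfs(
            state["tf_diff"], variab, target_group="tumor",
            fc_in=pars["fc_in"], fc_out_max=pars["fc_out_max"],
            alpha=pars["alpha"], multiplier=pars["mad_multiplier"],
            return_table=True)
        state.update(tf_variability=variab, tumor_tfs=selected,
                     tf_candidates=table)
        emit(stage, "tf_variability.tsv", lambda p: variab.to_csv(p, sep="\t"))
        emit(stage, "tf_candidates.tsv", lambda p: table.to_csv(p, sep="\t"))
        emit(stage, "tumor_tfs.txt",
             lambda p: pd.Series(selected).to_csv(p, index=False, header=False))

    elif stage == "cre":
        pars = config.stage_params("cre")
        atac_f, rna_f = state["atac_f"], state["rna_f"]
        labels = atac_f.obs.cell_type
        meta, meta_labels = cre.aggregate_to_metacells(
            atac_f, labels, group_size=pars["group_size"], seed=sseed)
        pairs = cre.compute_coaccessibility(
            meta, state["peaks"], window=pars["window"],
            coaccess_cutoff=pars["coaccess_cutoff"],
            base_penalty=pars["base_penalty"])
        atac_means = cre.type_mean_matrix(atac_f.X, labels, atac_f.var_names)
        rna_means = cre.type_mean_matrix(rna_f.X, labels, rna_f.var_names)
        links = cre.link_ccres(pairs, state["peaks"], state["genes"],
                               atac_means, rna_means, q_cut=pars["q_cut"])
        detection = detection_fraction_frame(atac_f.X, labels, atac_f.var_names)
        targets = []
        for m in state.get("tumor_tfs", []):
            targets.append(cre.identify_tf_targets(
                m, state["motifs"], links, state["peaks"], state["genes"],
                detection, "tumor", min_detection=pars["min_detection"]))
        tf_targets = (pd.concat(targets, ignore_index=True) if targets else
                      pd.DataFrame(columns=["tf", "target", "evidence", "peak"]))
        deg_genes = set(state["degs"].query("group == 'tumor'").feature)
        network = cre.build_network(tf_targets, deg_genes)
        assoc = features.dar_deg_association(
            state["dars"], state["degs"], state["peaks"], state["genes"],
            list(zip(links.distal_peak, links.gene)))
        state.update(coaccess=pairs, links=links, tf_targets=tf_targets,
                     network=network, dar_deg=assoc)
        emit(stage, "coaccessibility.tsv",
             lambda p: pairs.to_csv(p, sep="\t", index=False))
        emit(stage, "ccre_links.tsv",
             lambda p: links.to_csv(p, sep="\t", index=False))
        emit(stage, "tf_targets.tsv",
             lambda p: tf_targets.to_csv(p, sep="\t", index=False))
        emit(stage, "network.graphml",
             lambda p: _write_graphml(network, p))
        emit(stage, "dar_deg_association.tsv",
             lambda p: assoc["per_group"].rename("proportion").to_csv(p, sep="\t"))

    elif stage == "nmf":
        pars = config.stage_params("nmf")
        rna_f = state["rna_f"]
        programs = []
        log_by_sample = {}
        coph_all = {}
        for s in sorted(rna_f.obs["sample"].unique()):
            mask = ((rna_f.obs["sample"] == s)
                    & (rna_f.obs.cell_type == "tumor")).to_numpy()
            if mask.sum() < 20:
                continue
            logn = normalize_log1p(rna_f.X[mask])
            log_by_sample[s] = (logn, list(rna_f.var_names))
            rel = nmf.prepare_relative_expression(logn)
            res = nmf.run_nmf_range(rel, k_min=pars["k_min"], k_max=pars["k_max"],
                                    nrun=pars["nrun"], seed=sseed)
            coph = {k: v["cophenetic"] for k, v in res.items()}
            coph_all[s] = coph
            k_star = nmf.select_k_by_cophenetic_drop(coph)
            programs.extend(nmf.extract_programs(
                res[k_star]["H"], rna_f.var_names, s, k_star,
                top_n=pars["top_n"]))
        metas = nmf.derive_meta_programs(
            programs, log_by_sample,
            min_coverage_fraction=pars["min_coverage_fraction"], seed=sseed)
        state.update(programs=programs, meta_programs=metas)
        payload = {
            "cophenetic": coph_all,
            "programs": [{"sample": p.sample, "k": p.k, "index": p.index,
                          "top_genes": p.top_genes, "degenerate": p.degenerate}
                         for p in programs],
            "meta_programs": [{"members": m.members, "samples": m.samples,
                               "signature": m.signature} for m in metas],
        }
        emit(stage, "nmf_programs.json",
             lambda p: _write_json(payload, p))

    elif stage == "lr":
        pars = config.stage_params("lr")
        rna_f = state["rna_f"]
        lr_table = make_lr_table(state["truth"], list(rna_f.var_names),
                                 n_background=pars["n_background_pairs"],
                                 seed=sseed)
        means = interactions.compute_interaction_means(
            rna_f, rna_f.obs.cell_type, lr_table, min_frac=pars["min_frac"])
        tested = interactions.permutation_test(
            rna_f, rna_f.obs.cell_type, means, n_perm=pars["n_perm"], seed=sseed)
        results, counts = interactions.select_significant(
            tested, p_cut=pars["p_cut"], mean_cut=pars["mean_cut"])
        state.update(lr_table=lr_table, lr_results=results, lr_counts=counts)
        emit(stage, "lr_pairs.tsv",
             lambda p: lr_table.to_csv(p, sep="\t", index=False))
        emit(stage, "lr_results.tsv",
             lambda p: results.to_csv(p, sep="\t", index=False))
        emit(stage, "lr_counts.tsv", lambda p: counts.to_csv(p, sep="\t"))

    elif stage == "drugs":
        pars = config.stage_params("drugs")
        truth = state["truth"]
        z, approved = generate_drug_zscores(
            truth, n_drugs=pars["n_drugs"], n_genes=pars["n_genes"], seed=sseed)
        rows = []
        for tf in state.get("tumor_tfs", []):
            if tf in z.z.columns:
                for d in tumor_tf.screen_drugs(z, tf, z_cut=pars["z_cut"]):
                    rows.append((tf, d, float(z.z.loc[d, tf])))
        screen = pd.DataFrame(rows, columns=["tf", "drug", "z"])
        state.update(drug_z=z, drug_screen=screen)
        emit(stage, "drug_z.tsv", lambda p: z.z.to_csv(p, sep="\t"))
        emit(stage, "approved_drugs.txt",
             lambda p: pd.Series(z.approved).to_csv(p, index=False, header=False))
        emit(stage, "drug_screen.tsv",
             lambda p: screen.to_csv(p, sep="\t", index=False))


def make_lr_table(truth, gene_ids: list[str], n_background: int = 24,
                  seed: int = 0) -> pd.DataFrame:
    """Flat ligand-receptor pair table: planted pairs plus seeded background
    pairs drawn from genes not used by any planted pair."""
    planted = [(lig, rec) for lig, rec, _s, _t in (truth.lr_pairs if truth else [])]
    used = {g for p in planted for g in p}
    pool = [g for g in gene_ids if g not in used]
    rng = np.random.default_rng(seed)
    extra = []
    for _ in range(n_background):
        lig, rec = rng.choice(len(pool), size=2, replace=False)
        extra.append((pool[lig], pool[rec]))
    rows = planted + extra
    return pd.DataFrame(
        [(f"LR{i:03d}", lig, rec) for i, (lig, rec) in enumerate(rows)],
        columns=["pair_id", "ligand", "receptor"])


def _write_json(payload, path):
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _write_graphml(G, path):
    import networkx as nx
    H = G.copy()
    for u, v, data in H.edges(data=True):
        data["evidence"] = ";".join(f"{e}:{p}" for e, p in data["evidence"])
    nx.write_graphml(H, path)
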