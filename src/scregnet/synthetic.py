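"""Synthetic paired multiome generator with planted ground truth.

Emulates the data layout produced by a droplet-based paired scRNA-seq /
scATAC-seq experiment on a tumor microenvironment: discrete cell types with
negative-binomial marker expression, a tumor population with elevated
accessibility at peaks carrying planted "tumor TF" motifs, GC-content
covariates, promoter-proximal peaks, coupled distal-peak/gene pairs (planted
candidate cis-regulatory elements), intratumoral expression programs shared
across samples, planted ligand-receptor cluster pairs, and a drug-perturbation
Z-score screen with drugs that down-regulate the planted TF genes.

Counts are Gamma-Poisson (negative binomial) with lognormal per-cell depth.
Coordinates are 0-based half-open on two synthetic chromosomes. Per-peak GC
fraction is simulated from a Beta distribution (no sequence is generated).
Every planted effect lives on its own dedicated pool of genes/peaks so that
downstream recovery against the ground truth is unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

GENE_SPACING = 25_000
GENE_BODY_LEN = 5_000
PEAK_WIDTH = 500
FIRST_GENE_START = 50_000
CHROM_TAIL = 2_000_000


@dataclass
class SyntheticConfig:
    """Parameters of the planted-truth multiome.

    Defaults describe the study conditions used throughout the test-suite:
    3 samples x 4 cell types (one tumor) x 100 cells, 300 genes, 200 peaks,
    20 motifs of which 3 are tumor-specific with a 3x accessibility effect,
    20 fully coupled planted cCREs and 2 shared intratumoral programs.
    """

    n_samples: int = 3
    n_cell_types: int = 4  # cell type 0 is the tumor population
    cells_per_type_per_sample: int = 100
    n_genes: int = 300
    n_peaks: int = 200
    n_motifs: int = 20
    n_tumor_specific_motifs: int = 3
    tumor_motif_effect: float = 3.0  # accessibility multiplier, >= 1
    n_planted_ccres: int = 20
    ccre_effect: float = 1.0  # cross-cell-type coupling strength in [0, 1]
    n_programs: int = 2  # shared (meta) programs
    program_size: int = 30
    program_cell_fraction: float = 0.15
    n_private_programs: int = 1  # per-sample noise programs
    nb_dispersion: float = 0.3
    depth_lognormal_params: tuple[float, float] = (8.3, 0.35)  # RNA depth
    atac_depth_lognormal_params: tuple[float, float] = (8.2, 0.3)
    atac_nb_dispersion: float = 0.1  # scATAC counts are near-Poisson
    markers_per_type: int = 10
    marker_effect: float = 8.0
    promoter_peak_effect: float = 2.0
    hits_per_motif: int = 15
    ccre_type_sigma: float = 0.8  # log-sd of per-cell-type cCRE factors
    ccre_cell_tau: float = 0.8  # log-sd of the shared per-cell cCRE latent
    type_structure_sigma: float = 0.1  # mild background cell-type structure
    program_effect: float = 4.0
    intratumor_axis_sigma: float = 0.2  # per-sample continuous stress axis
    n_lr_pairs: int = 30
    n_planted_lr: int = 6
    lr_effect: float = 6.0
    gc_beta_params: tuple[float, float] = (6.0, 6.0)
    seed: int = 0

    def tumor_peak_pool_size(self) -> int:
        # tumor-specific TFs act as a module sharing binding sites, so their
        # hit sets are drawn from one dedicated pool slightly larger than a
        # single motif's hit count
        if self.n_tumor_specific_motifs == 0:
            return 0
        return int(np.ceil(1.6 * self.hits_per_motif))

    def validate(self) -> None:
        if min(self.n_samples, self.n_cell_types, self.cells_per_type_per_sample,
               self.n_genes, self.n_peaks, self.n_motifs) <= 0:
            raise ValueError("all size parameters must be positive")
        if self.tumor_motif_effect < 1:
            raise ValueError("tumor_motif_effect must be >= 1")
        if not 0 <= self.ccre_effect <= 1:
            raise ValueError("ccre_effect must lie in [0, 1]")
        if self.program_size < 30:
            raise ValueError("program_size must be >= 30")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_tumor_specific_motifs > self.n_motifs:
            raise ValueError("n_tumor_specific_motifs exceeds n_motifs")
        n_program_genes = (self.n_programs
                           + self.n_samples * self.n_private_programs) * self.program_size
        need_genes = (self.n_cell_types * self.markers_per_type
                      + self.n_planted_ccres + n_program_genes
                      + 2 * self.n_planted_lr)
        if need_genes > self.n_genes:
            raise ValueError(
                f"gene budget infeasible: markers+cCREs+programs+LR need "
                f"{need_genes} genes but n_genes={self.n_genes}")
        need_peaks = (2 * self.n_planted_ccres
                      + self.n_cell_types * self.markers_per_type
                      + self.tumor_peak_pool_size())
        if need_peaks > self.n_peaks:
            raise ValueError(
                f"peak budget infeasible: planted cCRE/marker/tumor-motif peaks "
                f"need {need_peaks} peaks but n_peaks={self.n_peaks}")
        if not 0 < self.program_cell_fraction <= 1:
            raise ValueError("program_cell_fraction must lie in (0, 1]")
        if 2 * self.n_planted_lr > self.n_lr_pairs:
            raise ValueError("n_planted_lr exceeds half of n_lr_pairs")


@dataclass
class GroundTruth:
    """Planted signals the downstream pipeline is expected to recover."""

    tumor_specific_motifs: list[str]
    ccre_links: list[tuple[str, str]]  # (distal peak id, gene id)
    ccre_promoter_peaks: dict[str, str]  # gene id -> promoter peak id
    program_genes: dict[str, dict[str, list[str]]]  # sample -> program -> genes
    meta_program_genes: dict[str, list[str]]  # shared program -> genes
    lr_pairs: list[tuple[str, str, str, str]]  # ligand, receptor, source, target
    effective_drugs: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["ccre_links"] = [list(t) for t in self.ccre_links]
        d["lr_pairs"] = [list(t) for t in self.lr_pairs]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["ccre_links"] = [tuple(t) for t in d["ccre_links"]]
        d["lr_pairs"] = [tuple(t) for t in d["lr_pairs"]]
        return cls(**d)


@dataclass
class MotifHits:
    """Binary peaks x motifs membership matrix."""

    matrix: sp.csr_matrix  # peaks x motifs, entries in {0, 1}
    peak_ids: list[str]
    motif_ids: list[str]

    def hit_peaks(self, motif_id: str) -> list[str]:
        j = self.motif_ids.index(motif_id)
        rows = self.matrix[:, j].nonzero()[0]
        return [self.peak_ids[i] for i in rows]


@dataclass
class DrugGeneZ:
    """Drug-perturbation differential-expression Z-scores with approval flags."""

    z: pd.DataFrame  # drugs x genes
    approved: list[str]


def _cell_type_names(n: int) -> list[str]:
    return ["tumor"] + [f"CT{i}" for i in range(1, n)]


def _place_distal(rng, positions, chrom_len, tss_list, bodies, n, anchor=None,
                  max_tries=2000):
    """Sample n intergenic midpoints (>1.25 kb from every TSS, outside bodies,
    >600 bp from previously placed peaks). With `anchor`, sample 15-120 kb away
    from it (same chromosome) for planted distal cCRE peaks."""
    out = []
    tss_arr = np.asarray(tss_list)
    for _ in range(n):
        for _try in range(max_tries):
            if anchor is None:
                pos = int(rng.integers(1000, chrom_len - 1000))
            else:
                off = rng.uniform(15_000, 120_000) * rng.choice([-1.0, 1.0])
                pos = int(np.clip(anchor + off, 1000, chrom_len - 1000))
            if np.abs(tss_arr - pos).min() <= 1250:
                continue
            if any(s <= pos < e for s, e in bodies):
                continue
            if positions and min(abs(pos - q) for q in positions[-400:]) <= 600:
                continue
            positions.append(pos)
            out.append(pos)
            break
        else:
            raise ValueError("could not place an intergenic peak; peak budget "
                             "too dense for the synthetic genome")
    return out


def generate_multiome(config: SyntheticConfig):
    """Generate a paired multiome with planted ground truth.

    Returns ``(rna, atac, peaks, motifs, genes, cells, truth)`` where `rna`
    and `atac` are :class:`anndata.AnnData` count matrices (cells x genes,
    cells x peaks), `peaks`/`genes`/`cells` are DataFrames and `truth` a
    :class:`GroundTruth`. Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # ------------------------------------------------------------------ genes
    n_g1 = (cfg.n_genes + 1) // 2
    gene_rows = []
    chrom_len = {}
    for i in range(cfg.n_genes):
        chrom = "chrS1" if i < n_g1 else "chrS2"
        j = i if i < n_g1 else i - n_g1
        start = FIRST_GENE_START + j * GENE_SPACING
        end = start + GENE_BODY_LEN
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end
        gene_rows.append((f"G{i:04d}", chrom, strand, tss, start, end))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"]
    ).set_index("gene_id")
    for chrom in ("chrS1", "chrS2"):
        sub = genes[genes.chrom == chrom]
        chrom_len[chrom] = int(sub.end.max()) + CHROM_TAIL

    # gene role pools (disjoint)
    perm = list(rng.permutation(cfg.n_genes))
    def take(k):
        return [f"G{perm.pop():04d}" for _ in range(k)]

    type_names = _cell_type_names(cfg.n_cell_types)
    marker_genes = {t: sorted(take(cfg.markers_per_type)) for t in type_names}
    ccre_genes = sorted(take(cfg.n_planted_ccres))
    shared_prog_genes = {f"MP{i + 1}": sorted(take(cfg.program_size))
                         for i in range(cfg.n_programs)}
    sample_names = [f"S{i + 1}" for i in range(cfg.n_samples)]
    private_prog_genes = {
        s: {f"{s}_private{j + 1}": sorted(take(cfg.program_size))
            for j in range(cfg.n_private_programs)}
        for s in sample_names}
    lr_gene_pool = take(2 * cfg.n_planted_lr)

    # ------------------------------------------------------------------ peaks
    # promoter peaks: planted cCRE genes + marker genes
    peak_specs = []  # (chrom, midpoint, role, payload)
    for g in ccre_genes:
        off = int(rng.integers(-300, 301))
        mid = int(genes.loc[g, "tss"]) + off
        peak_specs.append((genes.loc[g, "chrom"], mid, "ccre_promoter", g))
    for t in type_names:
        for g in marker_genes[t]:
            off = int(rng.integers(-300, 301))
            mid = int(genes.loc[g, "tss"]) + off
            peak_specs.append((genes.loc[g, "chrom"], mid, "marker_promoter", (t, g)))

    bodies_by_chrom = {
        c: list(zip(genes[genes.chrom == c].start, genes[genes.chrom == c].end))
        for c in chrom_len}
    tss_by_chrom = {c: list(genes[genes.chrom == c].tss) for c in chrom_len}
    placed = {c: [s[1] for s in peak_specs if s[0] == c] for c in chrom_len}

    # distal cCRE peaks, anchored near their gene's promoter
    for g in ccre_genes:
        c = genes.loc[g, "chrom"]
        mid = _place_distal(rng, placed[c], chrom_len[c], tss_by_chrom[c],
                            bodies_by_chrom[c], 1, anchor=int(genes.loc[g, "tss"]))[0]
        peak_specs.append((c, mid, "ccre_distal", g))

    # dedicated tumor-motif peak pool, shared by all tumor-specific motifs and
    # placed in the gene deserts at the chromosome tails (>600 kb from every
    # gene) so planted tumor accessibility never shares a co-accessibility
    # window with a promoter
    tumor_motif_ids = [f"TF{i + 1:02d}" for i in range(cfg.n_tumor_specific_motifs)]
    motif_ids = [f"TF{i + 1:02d}" for i in range(cfg.n_motifs)]
    for _ in range(cfg.tumor_peak_pool_size()):
        c = "chrS1" if rng.random() < 0.5 else "chrS2"
        L = chrom_len[c]
        for _try in range(2000):
            mid = int(rng.integers(L - 1_200_000, L - 200_000))
            if not placed[c] or min(abs(mid - q) for q in placed[c]) > 600:
                placed[c].append(mid)
                break
        else:
            raise ValueError("could not place a tumor-pool peak")
        peak_specs.append((c, mid, "tumor_pool", None))

    # filler peaks anywhere intergenic
    n_fill = cfg.n_peaks - len(peak_specs)
    for _ in range(n_fill):
        c = "chrS1" if rng.random() < 0.5 else "chrS2"
        mid = _place_distal(rng, placed[c], chrom_len[c], tss_by_chrom[c],
                            bodies_by_chrom[c], 1)[0]
        peak_specs.append((c, mid, "filler", None))

    # sort by coordinate, assign ids
    order = sorted(range(len(peak_specs)),
                   key=lambda i: (peak_specs[i][0], peak_specs[i][1]))
    peak_ids = [f"P{k:04d}" for k in range(len(order))]
    peak_rows, role_of = [], {}
    for k, i in enumerate(order):
        chrom, mid, role, payload = peak_specs[i]
        peak_rows.append((peak_ids[k], chrom, mid - PEAK_WIDTH // 2,
                          mid + PEAK_WIDTH // 2))
        role_of[peak_ids[k]] = (role, payload)
    peaks = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end"]
                         ).set_index("peak_id")
    peaks["gc"] = rng.beta(*cfg.gc_beta_params, size=len(peaks))

    pidx = {p: i for i, p in enumerate(peaks.index)}
    ccre_prom_peak = {role_of[p][1]: p for p in peaks.index
                      if role_of[p][0] == "ccre_promoter"}
    ccre_dist_peak = {role_of[p][1]: p for p in peaks.index
                      if role_of[p][0] == "ccre_distal"}
    marker_prom_peaks = {}  # type -> [(peak, gene)]
    for p in peaks.index:
        role, payload = role_of[p]
        if role == "marker_promoter":
            marker_prom_peaks.setdefault(payload[0], []).append((p, payload[1]))
    tumor_pool = sorted(p for p in peaks.index if role_of[p][0] == "tumor_pool")

    # ------------------------------------------------------------------ motifs
    # tumor motifs draw their hit sets from the shared tumor pool; every other
    # motif samples from the remaining (non-planted-effect) peaks so that
    # planted tumor accessibility is attributable to the planted motifs alone
    hit = sp.lil_matrix((cfg.n_peaks, cfg.n_motifs), dtype=np.int8)
    pool_idx = np.array([pidx[p] for p in tumor_pool], dtype=int)
    unplanted = {"filler", "marker_promoter"}
    other_idx = np.array([i for i, p in enumerate(peaks.index)
                          if role_of[p][0] in unplanted], dtype=int)
    for j, m in enumerate(motif_ids):
        if m in tumor_motif_ids:
            rows = pool_idx[rng.choice(len(pool_idx),
                                       size=min(cfg.hits_per_motif, len(pool_idx)),
                                       replace=False)]
        else:
            rows = other_idx[rng.choice(len(other_idx),
                                        size=min(cfg.hits_per_motif, len(other_idx)),
                                        replace=False)]
        hit[rows, j] = 1
    motifs = MotifHits(matrix=hit.tocsr(), peak_ids=list(peaks.index),
                       motif_ids=motif_ids)
    tumor_motif_peaks = {m: motifs.hit_peaks(m) for m in tumor_motif_ids}

    # ------------------------------------------------------------------ cells
    cell_rows = []
    for s in sample_names:
        k = 0
        for t in type_names:
            for _ in range(cfg.cells_per_type_per_sample):
                cell_rows.append((f"{s}_c{k:04d}", s, t))
                k += 1
    cells = pd.DataFrame(cell_rows, columns=["cell_id", "sample", "cell_type"]
                         ).set_index("cell_id")
    n_cells = len(cells)
    type_of = cells.cell_type.to_numpy()
    sample_of = cells["sample"].to_numpy()
    t_index = {t: i for i, t in enumerate(type_names)}
    t_codes = np.array([t_index[t] for t in type_of])

    # program cell membership: independent Bernoulli draws per (cell,
    # program), so programs are independent expression axes (a cell may run
    # several programs, or none) rather than a partition of the tumor cells
    program_cells: dict[str, dict[str, list[str]]] = {}
    program_genes: dict[str, dict[str, list[str]]] = {}
    for s in sample_names:
        tumor_cells = cells.index[(sample_of == s) & (type_of == "tumor")]
        progs = dict(shared_prog_genes)
        progs.update(private_prog_genes[s])
        program_cells[s], program_genes[s] = {}, {}
        for name in progs:
            member = rng.random(len(tumor_cells)) < cfg.program_cell_fraction
            program_cells[s][name] = list(tumor_cells[member])
            program_genes[s][name] = list(progs[name])

    # planted L-R pairs
    lr_records = []
    nontumor = [t for t in type_names if t != "tumor"]
    for i in range(cfg.n_planted_lr):
        lig, rec = lr_gene_pool[2 * i], lr_gene_pool[2 * i + 1]
        src = "tumor" if i % 2 == 0 else nontumor[i % len(nontumor)]
        tgt = nontumor[(i + 1) % len(nontumor)] if src == "tumor" else "tumor"
        lr_records.append((lig, rec, src, tgt))

    # ------------------------------------------------------- cell-type factors
    T = cfg.n_cell_types
    ccre_u = rng.normal(0, 1, size=(cfg.n_planted_ccres, T))  # shared log-factor
    ccre_noise = rng.normal(0, 1, size=(cfg.n_planted_ccres, T))
    c_eff = cfg.ccre_effect
    ccre_u_peak = c_eff * ccre_u + np.sqrt(1 - c_eff ** 2) * ccre_noise

    # ------------------------------------------------------------- ATAC rates
    gidx = {g: i for i, g in enumerate(genes.index)}
    log_lam = rng.normal(0, 0.5, size=cfg.n_peaks)
    type_log_p = rng.normal(0, cfg.type_structure_sigma, size=(T, cfg.n_peaks))
    sig = cfg.ccre_type_sigma
    for i, g in enumerate(ccre_genes):
        for col, fac in ((pidx[ccre_prom_peak[g]], ccre_u_peak[i]),
                         (pidx[ccre_dist_peak[g]], ccre_u_peak[i])):
            type_log_p[:, col] = sig * fac  # replaces mild structure
    for t in type_names:
        for p, _g in marker_prom_peaks.get(t, []):
            type_log_p[t_index[t], pidx[p]] += np.log(cfg.promoter_peak_effect)
    # The tumor multiplier raises a planted peak's across-cell mean by
    # 1 + (effect-1)/n_cell_types; compensate the baseline so planted peaks
    # stay spread over the accessibility spectrum instead of clustering at
    # its top (which would bias accessibility-matched background sampling
    # toward other planted peaks).
    mean_shift = np.log1p((cfg.tumor_motif_effect - 1.0) / T)
    tumor_hit_union = sorted({p for m in tumor_motif_ids
                              for p in tumor_motif_peaks[m]})
    for p in tumor_hit_union:
        type_log_p[t_index["tumor"], pidx[p]] += np.log(cfg.tumor_motif_effect)
        log_lam[pidx[p]] -= mean_shift

    cell_extra_p = np.zeros((n_cells, cfg.n_peaks))
    tau = cfg.ccre_cell_tau
    ccre_z = rng.normal(0, 1, size=(n_cells, cfg.n_planted_ccres))
    for i, g in enumerate(ccre_genes):
        cell_extra_p[:, pidx[ccre_prom_peak[g]]] += tau * ccre_z[:, i]
        cell_extra_p[:, pidx[ccre_dist_peak[g]]] += tau * ccre_z[:, i]

    atac_rate = np.exp(log_lam[None, :] + type_log_p[t_codes] + cell_extra_p)
    # same row-sum compensation as on the RNA side: planted tumor-pool and
    # marker-promoter load must not dilute cCRE peaks type-dependently
    ccre_peak_idx = [pidx[ccre_prom_peak[g]] for g in ccre_genes] +         [pidx[ccre_dist_peak[g]] for g in ccre_genes]
    row_sums_p = atac_rate.sum(axis=1)
    type_mean_sum_p = np.array([row_sums_p[t_codes == t].mean()
                                for t in range(T)])
    rel_p = type_mean_sum_p / np.exp(np.mean(np.log(type_mean_sum_p)))
    atac_rate[:, ccre_peak_idx] *= rel_p[t_codes][:, None]
    atac_prob = atac_rate / atac_rate.sum(axis=1, keepdims=True)
    mu, sd = cfg.atac_depth_lognormal_params
    atac_depth = rng.lognormal(mu, sd, size=n_cells)
    atac_mean = atac_prob * atac_depth[:, None]
    atac_shape = 1.0 / cfg.atac_nb_dispersion
    atac_counts = rng.poisson(
        rng.gamma(atac_shape, atac_mean * cfg.atac_nb_dispersion))
    shape = 1.0 / cfg.nb_dispersion

    # -------------------------------------------------------------- RNA rates
    base_g = rng.normal(0, 1.0, size=cfg.n_genes)
    type_log_g = rng.normal(0, cfg.type_structure_sigma, size=(T, cfg.n_genes))
    for i, g in enumerate(ccre_genes):
        type_log_g[:, gidx[g]] = sig * ccre_u[i]
    for t in type_names:
        for g in marker_genes[t]:
            type_log_g[t_index[t], gidx[g]] += np.log(cfg.marker_effect)
    for lig, rec, src, tgt in lr_records:
        type_log_g[t_index[src], gidx[lig]] += np.log(cfg.lr_effect)
        type_log_g[t_index[tgt], gidx[rec]] += np.log(cfg.lr_effect)

    cell_extra_g = np.zeros((n_cells, cfg.n_genes))
    cell_pos = {c: i for i, c in enumerate(cells.index)}
    for s in sample_names:
        for name, members in program_cells[s].items():
            rows = [cell_pos[c] for c in members]
            cols = [gidx[g] for g in program_genes[s][name]]
            cell_extra_g[np.ix_(rows, cols)] += np.log(cfg.program_effect)
    # sample-specific continuous intratumoral axis (e.g. dissociation-stress
    # or partial-EMT gradients): one random loading vector over all genes per
    # sample, scaled by a per-cell N(0,1) intensity in that sample's tumor
    # cells; gene composition matches the genome, unlike the planted programs
    ccre_gene_idx = [gidx[g] for g in ccre_genes]
    for s in sample_names:
        w_s = rng.normal(0, 1, size=cfg.n_genes)
        w_s[ccre_gene_idx] = 0.0  # keep planted cCRE coupling attributable
        rows = np.flatnonzero((sample_of == s) & (type_of == "tumor"))
        z = rng.normal(0, 1, size=len(rows))
        cell_extra_g[rows] += cfg.intratumor_axis_sigma * np.outer(z, w_s)

    rna_rate = np.exp(base_g[None, :] + type_log_g[t_codes] + cell_extra_g)
    # Program/marker load inflates tumor row sums, which would dilute the
    # planted cCRE genes' relative abundance in a type-dependent way and break
    # the generator's contract that cCRE expression tracks accessibility with
    # strength ccre_effect. Compensate their rates by each type's mean
    # relative row sum.
    row_sums = rna_rate.sum(axis=1)
    type_mean_sum = np.array([row_sums[t_codes == t].mean() for t in range(T)])
    rel = type_mean_sum / np.exp(np.mean(np.log(type_mean_sum)))
    rna_rate[:, ccre_gene_idx] *= rel[t_codes][:, None]
    rna_prob = rna_rate / rna_rate.sum(axis=1, keepdims=True)
    mu, sd = cfg.depth_lognormal_params
    rna_depth = rng.lognormal(mu, sd, size=n_cells)
    rna_mean = rna_prob * rna_depth[:, None]
    rna_counts = rng.poisson(rng.gamma(shape, rna_mean * cfg.nb_dispersion))

    # -------------------------------------------------------------- QC metrics
    cells = cells.copy()
    cells["n_umi"] = rna_counts.sum(axis=1)
    cells["n_genes"] = (rna_counts > 0).sum(axis=1)
    cells["mito_fraction"] = rng.beta(2, 38, size=n_cells)
    cells["peak_region_fragments"] = atac_counts.sum(axis=1)
    cells["frip"] = rng.beta(8, 12, size=n_cells)
    cells["blacklist_ratio"] = rng.beta(2, 198, size=n_cells)
    cells["nucleosome_signal"] = rng.gamma(4.0, 0.5, size=n_cells)
    cells["tss_enrichment"] = rng.gamma(9.0, 0.75, size=n_cells)

    rna = ad.AnnData(
        X=sp.csr_matrix(rna_counts.astype(np.int32)),
        obs=cells[["sample", "cell_type"]].copy(),
        var=pd.DataFrame(index=genes.index.copy()),
    )
    atac = ad.AnnData(
        X=sp.csr_matrix(atac_counts.astype(np.int32)),
        obs=cells[["sample", "cell_type"]].copy(),
        var=pd.DataFrame(index=peaks.index.copy()),
    )

    truth = GroundTruth(
        tumor_specific_motifs=list(tumor_motif_ids),
        ccre_links=[(ccre_dist_peak[g], g) for g in ccre_genes],
        ccre_promoter_peaks=dict(sorted(ccre_prom_peak.items())),
        program_genes=program_genes,
        meta_program_genes={k: list(v) for k, v in shared_prog_genes.items()},
        lr_pairs=lr_records,
    )
    return rna, atac, peaks, motifs, genes, cells, truth


def generate_drug_zscores(truth: GroundTruth, n_drugs: int = 60,
                          n_genes: int = 120, seed: int = 0,
                          n_drugs_per_tf: int = 2):
    """Simulate a drug x gene perturbation Z-score matrix.

    Background entries are N(0,1). For every planted tumor-specific motif, a
    small set of "effective" drugs gets Z < -2 at the motif's TF gene; the
    approved list contains every effective drug plus a random subset of the
    rest. Records the planted map in ``truth.effective_drugs``.
    """
    rng = np.random.default_rng(seed)
    tfs = list(truth.tumor_specific_motifs)
    if n_drugs < n_drugs_per_tf * len(tfs):
        raise ValueError("n_drugs smaller than the number of planted "
                         "effective drugs")
    if n_genes < len(tfs):
        raise ValueError("n_genes must cover all planted TF genes")
    drug_ids = [f"D{i:03d}" for i in range(n_drugs)]
    gene_cols = tfs + [f"BG{i:03d}" for i in range(n_genes - len(tfs))]
    z = rng.normal(0, 1, size=(n_drugs, n_genes))
    effective: dict[str, list[str]] = {}
    for j, tf in enumerate(tfs):
        picks = rng.choice(n_drugs, size=n_drugs_per_tf, replace=False)
        for d in picks:
            z[d, j] = rng.uniform(-6.0, -3.0)
        effective[tf] = sorted(drug_ids[d] for d in picks)
    planted = sorted({d for ds in effective.values() for d in ds})
    extra = [d for d in drug_ids if d not in planted and rng.random() < 0.3]
    approved = sorted(planted + extra)
    truth.effective_drugs = effective
    zdf = pd.DataFrame(z, index=drug_ids, columns=gene_cols)
    return DrugGeneZ(z=zdf, approved=approved), approved
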