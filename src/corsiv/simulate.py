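"""Synthetic multi-individual, multi-tissue methylome generator.

The generator emulates the statistical structure the screen exploits in a
cohort of ~10 donors with WGBS of three germ-layer tissues at ~40x depth:

* **systemic regions** — interindividual variation shared by all tissues,
  either genotype-driven (an additive cis effect of a nearby "driver" SNV)
  or stochastic (epigenetically metastable: one latent level per individual,
  drawn independently of genotype);
* **tissue-specific DMRs** — a fixed per-tissue methylation offset identical
  across individuals, the screen's principal confusable class;
* **null background** — one population-level methylation value per bin plus
  read noise;
* a per-(bin, tissue) landscape offset shared by all individuals, giving the
  genome-wide cluster-by-tissue signature that real methylomes show;
* beta-binomial read noise (Poisson per-CpG depth, configurable
  overdispersion) and haplotype-block LD for genotypes.

Planted ground truth is returned as a table so that every pipeline stage has
a known answer to be scored against.  Identical seeds give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .binmatrix import BinMatrix

TRUTH_COLUMNS = [
    "region_id", "chrom", "start", "end", "cls", "iir",
    "driver_snv", "effect_pp_per_allele", "dmr_tissue", "dmr_offset",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the screen's design: 10 individuals, three germ-layer
    tissues, ~40x sequencing depth, and a 10-Mb toy genome (2 chromosomes x
    5 Mb) carrying 100 planted systemic regions (half genotype-driven, half
    stochastic) with population IIR in 30-70 percentage points, and 200
    tissue-specific DMRs.
    """

    n_individuals: int = 10
    tissues: tuple[str, ...] = ("brain", "heart", "thyroid")
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    bin_size: int = 100
    cpg_rate: float = 2.0            # mean CpGs per background bin (Poisson)
    mean_depth: float = 40.0         # per-CpG per-sample Poisson mean
    overdispersion: float = 0.05     # beta-binomial rho
    n_systemic_genetic: int = 50
    n_systemic_stochastic: int = 50
    n_tissue_dmr: int = 200
    iir_range: tuple[float, float] = (30.0, 70.0)   # percentage points
    dmr_offset: float = 30.0         # pp shift of the DMR tissue
    region_bins: tuple[int, int] = (3, 10)          # planted length, inclusive
    planted_cpg_min: int = 2         # CpGs per planted bin: min + Poisson(extra)
    planted_cpg_extra: float = 1.0
    tissue_profile_sd: float = 5.0   # pp, per-(bin, tissue) landscape offset
    baseline_range: tuple[float, float] = (10.0, 90.0)
    # genotypes
    snv_spacing: int = 2_000
    block_length: int = 30_000       # haplotype-block span
    copy_prob: float = 0.95          # P(SNV allele copies block haplotype state)
    maf_range: tuple[float, float] = (0.2, 0.5)
    seed: int | None = None

    def individuals(self) -> list[str]:
        return [f"I{k:02d}" for k in range(1, self.n_individuals + 1)]


@dataclass
class SimResult:
    tables: dict[tuple[str, str], pd.DataFrame]
    genotypes: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def bin_matrix(self) -> BinMatrix:
        from .binmatrix import bin_methylation

        return bin_methylation(self.tables, bin_size=self.config.bin_size)


# ---------------------------------------------------------------------------
# genotypes


def _draw_block(rng, n_snv, n_ind, f, copy_prob):
    """Haplotype-block genotypes: two haplotypes per individual; each SNV
    copies the block's haplotype state with probability ``copy_prob`` (giving
    within-block LD), else draws an independent allele at frequency ``f``."""
    hap_state = rng.random((n_ind, 2)) < f            # block state per haplotype
    copies = rng.random((n_snv, n_ind, 2)) < copy_prob
    indep = rng.random((n_snv, n_ind, 2)) < f
    alleles = np.where(copies, hap_state[None, :, :], indep)
    return alleles.sum(axis=2).astype(np.int8)        # additive 0/1/2


def simulate_genotypes(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Biallelic SNV genotypes with haplotype-block LD.

    SNVs are placed every ``snv_spacing`` bp and grouped into blocks of
    ``block_length`` bp; within-block pairs are in strong LD (expected r^2
    ~ copy_prob^2-driven), across blocks independent.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    inds = cfg.individuals()
    frames = []
    for chrom, size in cfg.chrom_sizes.items():
        pos = np.arange(cfg.snv_spacing // 2, size, cfg.snv_spacing)
        block = pos // cfg.block_length
        geno = np.empty((len(pos), cfg.n_individuals), dtype=np.int8)
        for b in np.unique(block):
            sel = block == b
            f = rng.uniform(*cfg.maf_range)
            geno[sel] = _draw_block(rng, sel.sum(), cfg.n_individuals, f, cfg.copy_prob)
        df = pd.DataFrame(
            {
                "snv_id": [f"{chrom}_snv{p}" for p in pos],
                "chrom": chrom,
                "pos": pos,
                "block": block,
            }
        )
        for k, ind in enumerate(inds):
            df[ind] = geno[:, k]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _force_trigenotypic(gt: pd.DataFrame, snv_row: int, cfg: SimConfig, rng) -> None:
    """Redraw a driver SNV's whole haplotype block until the driver carries
    all three genotypes in the cohort (drivers represent common variants
    informative in-sample; block-level redraw preserves LD structure)."""
    inds = cfg.individuals()
    chrom = gt.at[snv_row, "chrom"]
    block = gt.at[snv_row, "block"]
    sel = (gt["chrom"] == chrom) & (gt["block"] == block)
    idx = np.flatnonzero(sel.to_numpy())
    for _ in range(500):
        g = gt.loc[snv_row, inds].to_numpy(dtype=int)
        if {0, 1, 2}.issubset(set(g.tolist())):
            return
        f = rng.uniform(0.35, 0.5)
        geno = _draw_block(rng, len(idx), cfg.n_individuals, f, cfg.copy_prob)
        gt.loc[gt.index[idx], inds] = geno
    raise RuntimeError("could not draw a tri-genotypic driver SNV")


# ---------------------------------------------------------------------------
# cohort


def _place_regions(rng, n_bins_by_chrom, counts, length_range):
    """Non-overlapping placements (chrom, start_bin, n_bins, cls) on the bin
    grid, with a 1-bin spacer between planted regions."""
    chroms = list(n_bins_by_chrom)
    occupied = {c: np.zeros(n_bins_by_chrom[c], dtype=bool) for c in chroms}
    placements = []
    lo, hi = length_range
    for cls, n in counts.items():
        for _ in range(n):
            for _try in range(10_000):
                chrom = chroms[rng.integers(len(chroms))]
                nb = int(rng.integers(lo, hi + 1))
                nbc = n_bins_by_chrom[chrom]
                if nbc <= nb + 2:
                    continue
                s = int(rng.integers(1, nbc - nb - 1))
                if occupied[chrom][s - 1 : s + nb + 1].any():
                    continue
                occupied[chrom][s : s + nb] = True
                placements.append((cls, chrom, s, nb))
                break
            else:
                raise RuntimeError("planted regions exceed genome capacity")
    return placements


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Generate per-sample CpG call tables, genotypes, and planted truth.

    Latent per-region structure (see module docstring) is converted to
    observed counts CpG by CpG: depth ~ Poisson(mean_depth), methylated reads
    ~ beta-binomial(depth, latent level, overdispersion).  Latent levels are
    clamped to [2, 98] percent to avoid boundary degeneracies.
    """
    if cfg.seed is None:
        raise ValueError("SimConfig.seed is mandatory for simulation")
    rng = np.random.default_rng(cfg.seed)
    inds = cfg.individuals()
    tissues = list(cfg.tissues)
    n_ind, n_tis = cfg.n_individuals, len(tissues)

    genotypes = simulate_genotypes(cfg, rng)

    n_bins_by_chrom = {c: s // cfg.bin_size for c, s in cfg.chrom_sizes.items()}
    chroms = list(n_bins_by_chrom)
    offsets = np.cumsum([0] + [n_bins_by_chrom[c] for c in chroms])
    total_bins = offsets[-1]

    counts = {
        "systemic_genetic": cfg.n_systemic_genetic,
        "systemic_stochastic": cfg.n_systemic_stochastic,
        "tissue_dmr": cfg.n_tissue_dmr,
    }
    placements = _place_regions(rng, n_bins_by_chrom, counts, cfg.region_bins)

    # latent levels: population baseline per bin, per-individual deviations
    base = rng.uniform(*cfg.baseline_range, size=total_bins)
    levels = np.broadcast_to(base[:, None], (total_bins, n_ind)).copy()
    toff = rng.normal(0.0, cfg.tissue_profile_sd, size=(total_bins, n_tis))
    dmr_extra = np.zeros((total_bins, n_tis))
    planted_mask = np.zeros(total_bins, dtype=bool)

    truth_rows = []
    snv_pos_by_chrom = {
        c: genotypes.loc[genotypes["chrom"] == c, "pos"].to_numpy() for c in chroms
    }
    snv_rows_by_chrom = {
        c: genotypes.index[genotypes["chrom"] == c].to_numpy() for c in chroms
    }

    for k, (cls, chrom, s_bin, nb) in enumerate(placements):
        ci = chroms.index(chrom)
        g0 = offsets[ci]
        rows = slice(g0 + s_bin, g0 + s_bin + nb)
        start = s_bin * cfg.bin_size
        end = start + nb * cfg.bin_size
        planted_mask[rows] = True
        iir = np.nan
        driver = ""
        effect = np.nan
        dmr_tissue = ""
        dmr_off = np.nan
        if cls == "systemic_stochastic":
            iir = rng.uniform(*cfg.iir_range)
            b = rng.uniform(iir / 2 + 2, 98 - iir / 2)
            u = rng.random(n_ind)
            # rescale uniform draws so the cohort realizes the planted IIR
            lv = b - iir / 2 + iir * (u - u.min()) / (u.max() - u.min())
            levels[rows] = lv[None, :]
        elif cls == "systemic_genetic":
            iir = rng.uniform(*cfg.iir_range)
            mid = (start + end) // 2
            near = np.argmin(np.abs(snv_pos_by_chrom[chrom] - mid))
            snv_row = int(snv_rows_by_chrom[chrom][near])
            _force_trigenotypic(genotypes, snv_row, cfg, rng)
            g = genotypes.loc[snv_row, inds].to_numpy(dtype=float)
            effect = iir / 2.0
            b = rng.uniform(iir / 2 + 2, 98 - iir / 2)
            levels[rows] = (b + effect * (g - 1.0))[None, :]
            driver = genotypes.at[snv_row, "snv_id"]
        elif cls == "tissue_dmr":
            t = int(rng.integers(n_tis))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            dmr_off = sign * cfg.dmr_offset
            b = rng.uniform(
                max(cfg.dmr_offset + 4, 10), min(94 - cfg.dmr_offset, 90)
            )
            levels[rows] = b
            dmr_extra[rows, t] = dmr_off
            dmr_tissue = tissues[t]
        truth_rows.append(
            (f"R{k:04d}", chrom, start, end, cls, iir, driver, effect,
             dmr_tissue, dmr_off)
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    # CpG placement: background bins Poisson(cpg_rate) CpGs; planted bins are
    # CpG-dense (min + Poisson(extra)); offsets jittered-uniform, distinct
    k_bins = rng.poisson(cfg.cpg_rate, size=total_bins)
    k_bins[planted_mask] = cfg.planted_cpg_min + rng.poisson(
        cfg.planted_cpg_extra, size=int(planted_mask.sum())
    )
    total_cpgs = int(k_bins.sum())
    bin_of_cpg = np.repeat(np.arange(total_bins), k_bins)
    within = np.concatenate([np.arange(k) for k in k_bins if k > 0])
    jitter = rng.random(total_cpgs)
    off = np.floor(
        (within + jitter) * (cfg.bin_size / np.repeat(k_bins[k_bins > 0], k_bins[k_bins > 0]))
    ).astype(np.int64)
    chrom_of_bin = np.repeat(np.arange(len(chroms)), [n_bins_by_chrom[c] for c in chroms])
    bin_start = (
        np.concatenate([np.arange(n_bins_by_chrom[c]) for c in chroms]) * cfg.bin_size
    )
    pos_of_cpg = bin_start[bin_of_cpg] + off
    chrom_names = np.array(chroms, dtype=object)
    chrom_of_cpg = chrom_names[chrom_of_bin[bin_of_cpg]]

    rho = cfg.overdispersion
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for i, ind in enumerate(inds):
        for t, tis in enumerate(tissues):
            mu = np.clip(levels[:, i] + toff[:, t] + dmr_extra[:, t], 2.0, 98.0) / 100.0
            mu_cpg = mu[bin_of_cpg]
            depth = rng.poisson(cfg.mean_depth, size=total_cpgs)
            if rho > 0:
                conc = (1.0 - rho) / rho
                p = rng.beta(mu_cpg * conc, (1.0 - mu_cpg) * conc)
            else:
                p = mu_cpg
            nm = rng.binomial(depth, p)
            keep = depth > 0
            tables[(ind, tis)] = pd.DataFrame(
                {
                    "chrom": chrom_of_cpg[keep],
                    "pos": pos_of_cpg[keep],
                    "n_meth": nm[keep],
                    "n_total": depth[keep],
                }
            )
    genotypes = genotypes.drop(columns=["block"])
    return SimResult(tables=tables, genotypes=genotypes, truth=truth, config=cfg)


def write_cohort(sim: SimResult, outdir) -> None:
    """Write the cohort in the formats the readers consume (coverage files,
    genotype TSV, truth TSV, chromosome sizes)."""
    from .io import write_cpg_table, write_genotypes, write_chrom_sizes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (ind, tis), df in sim.tables.items():
        write_cpg_table(df, outdir / f"{ind}_{tis}.cov")
    write_genotypes(sim.genotypes, outdir / "genotypes.tsv")
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_chrom_sizes(dict(sim.config.chrom_sizes), outdir / "chrom.sizes")


# ---------------------------------------------------------------------------
# seasonality cohort


def simulate_seasonal_cohort(
    n_subjects: int = 233,
    amplitude: float = 5.0,
    peak_day: float = 240.0,
    noise_sd: float = 5.0,
    baseline: float = 50.0,
    n_seasonal: int = 50,
    n_null: int = 150,
    seed: int | None = None,
):
    """Cohort with a sinusoidal season-of-conception effect at planted sites.

    Per subject: methylation = baseline + amplitude * cos(2*pi*(d - peak_day)
    / 365.25) + Gaussian noise, conception dates uniform over the year.

    Returns ``(meth, days, classes)``: a subjects x sites DataFrame, the
    conception day-of-year per subject, and a per-site class Series
    (planted sites labelled ``corsiv``; null sites split between ``control``
    and ``tdmr``).
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    period = 365.25
    days = rng.uniform(0, period, size=n_subjects)
    sites, classes, cols = [], [], []
    signal = amplitude * np.cos(2 * np.pi * (days - peak_day) / period)
    for j in range(n_seasonal):
        cols.append(baseline + signal + rng.normal(0, noise_sd, n_subjects))
        sites.append(f"season_{j:03d}")
        classes.append("corsiv")
    for j in range(n_null):
        cols.append(baseline + rng.normal(0, noise_sd, n_subjects))
        sites.append(f"null_{j:03d}")
        classes.append("control" if j % 2 == 0 else "tdmr")
    meth = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((n_subjects, 0)),
        columns=sites,
        index=[f"S{k:03d}" for k in range(n_subjects)],
    )
    return meth, days, pd.Series(classes, index=sites, name="cls")


# ---------------------------------------------------------------------------
# decay locus


def simulate_decay_locus(
    seed: int,
    n_individuals: int = 10,
    tissues: tuple[str, ...] = ("brain", "heart", "thyroid"),
    span: int = 20_000,
    snv_spacing: int = 1_000,
    flip_prob: float = 0.05,
    effect: float = 15.0,
    mean_depth: float = 40.0,
    overdispersion: float = 0.05,
    cpgs_per_bin: int = 2,
    bin_size: int = 100,
    corsiv_bins: int = 3,
    ld: bool = True,
    genetic: bool = True,
):
    """One locus for methylation-decay vs LD-decay analysis.

    With ``ld=True`` SNV alleles follow a Markov chain along each haplotype
    (adjacent-SNV correlation 1 - 2*flip_prob, so r^2 decays geometrically
    with distance); with ``genetic=True`` each bin's methylation is driven by
    its nearest SNV, so the methylation correlation profile decays in
    parallel with LD.  ``ld=False, genetic=False`` gives a stochastic
    systemic region in an LD-free background (the pure-epigenetic analogue).

    Returns ``(bm, genotypes, region)`` where ``region`` has the member bin
    indices of the central correlated region.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    width = corsiv_bins * bin_size
    length = 2 * span + width
    c_start, c_end = span, span + width
    n_bins = length // bin_size
    n_tis = len(tissues)
    inds = [f"I{k:02d}" for k in range(1, n_individuals + 1)]

    snv_pos = np.arange(snv_spacing // 2, length, snv_spacing)
    # guarantee one SNV inside the central region
    mid = (c_start + c_end) // 2
    snv_pos[np.argmin(np.abs(snv_pos - mid))] = mid
    snv_pos = np.sort(snv_pos)
    n_snv = len(snv_pos)

    if ld:
        hap = np.zeros((n_snv, n_individuals, 2), dtype=bool)
        hap[0] = rng.random((n_individuals, 2)) < 0.5
        flips = rng.random((n_snv - 1, n_individuals, 2)) < flip_prob
        for s in range(1, n_snv):
            hap[s] = hap[s - 1] ^ flips[s - 1]
        geno = hap.sum(axis=2).astype(float)
    else:
        geno = (rng.random((n_snv, n_individuals, 2)) < 0.5).sum(axis=2).astype(float)

    bin_starts = np.arange(n_bins) * bin_size
    bin_mid = bin_starts + bin_size // 2
    levels = np.empty((n_bins, n_individuals))
    if genetic:
        nearest = np.argmin(np.abs(bin_mid[:, None] - snv_pos[None, :]), axis=1)
        levels[:] = 50.0 + effect * (geno[nearest] - 1.0)
    else:
        base = rng.uniform(30, 70, size=n_bins)
        levels[:] = base[:, None]
        in_region = (bin_starts >= c_start) & (bin_starts < c_end)
        u = rng.random(n_individuals)
        lv = 30 + 40 * (u - u.min()) / (u.max() - u.min())
        levels[in_region] = lv[None, :]

    rho = overdispersion
    samples = [(ind, tis) for ind in inds for tis in tissues]
    mc = np.zeros((n_bins, len(samples)), dtype=np.int64)
    tc = np.zeros_like(mc)
    for j, (ind, tis) in enumerate(samples):
        i = inds.index(ind)
        mu = np.clip(levels[:, i], 2, 98) / 100.0
        mu_cpg = np.repeat(mu, cpgs_per_bin)
        depth = rng.poisson(mean_depth, size=n_bins * cpgs_per_bin)
        conc = (1.0 - rho) / rho
        p = rng.beta(mu_cpg * conc, (1.0 - mu_cpg) * conc)
        nm = rng.binomial(depth, p)
        mc[:, j] = nm.reshape(n_bins, cpgs_per_bin).sum(axis=1)
        tc[:, j] = depth.reshape(n_bins, cpgs_per_bin).sum(axis=1)

    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": bin_starts,
            "end": bin_starts + bin_size,
            "n_cpgs": cpgs_per_bin,
        }
    )
    bm = BinMatrix(bins=bins, samples=samples, meth_counts=mc, total_counts=tc,
                   bin_size=bin_size)
    gt = pd.DataFrame(
        {"snv_id": [f"snv{p}" for p in snv_pos], "chrom": chrom, "pos": snv_pos}
    )
    for k, ind in enumerate(inds):
        gt[ind] = geno[:, k]
    region = {
        "region_id": "locus",
        "chrom": chrom,
        "start": c_start,
        "end": c_end,
        "bin_ids": np.flatnonzero(
            (bin_starts >= c_start) & (bin_starts < c_end)
        ),
    }
    return bm, gt, region


# ---------------------------------------------------------------------------
# methylation-expression cohort


def simulate_meth_expr_cohort(
    n_subjects: int = 200,
    n_linked: int = 50,
    n_null: int = 50,
    meth_noise: float = 5.0,
    expr_noise: float = 0.5,
    seed: int | None = None,
):
    """Cohort where a shared latent driver couples one tissue's methylation
    to expression of the associated gene in all tissues (linked genes);
    null genes have independent expression.

    Returns ``(meth, expr, mapping)``: subjects x CoRSIVs methylation in the
    assayed tissue, a dict of subjects x genes expression per tissue, and the
    CoRSIV <-> gene map.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    subjects = [f"S{k:03d}" for k in range(n_subjects)]
    tissues = ["adipose", "skin", "lcl"]
    n_genes = n_linked + n_null
    genes = [f"G{k:03d}" for k in range(n_genes)]
    corsivs = [f"C{k:03d}" for k in range(n_genes)]

    z = rng.normal(size=(n_subjects, n_genes))
    meth = 50 + 10 * z + rng.normal(0, meth_noise, size=z.shape)
    expr = {}
    for t in tissues:
        e = rng.normal(0, expr_noise, size=z.shape)
        e[:, :n_linked] += z[:, :n_linked]
        expr[t] = pd.DataFrame(e, index=subjects, columns=genes)
    meth_df = pd.DataFrame(meth, index=subjects, columns=corsivs)
    mapping = pd.DataFrame(
        {"corsiv_id": corsivs, "gene_id": genes,
         "linked": [True] * n_linked + [False] * n_null}
    )
    return meth_df, expr, mapping
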