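"""Synthetic F2-intercross generator with planted expression/phenotype genetics.

The generator emulates the structure of an F2 resource population bred from
two divergent founder lines (a handful of founder sires from one line, dams
from the other, an F1 generation, and an F2 generation produced by crossing
F1 animals).  Meiosis follows the Haldane model: crossover counts are Poisson
in the genetic map length with no interference, which gives the long-range
linkage disequilibrium characteristic of such crosses (dosage correlation
exp(-2d) at genetic distance d Morgans for line-divergent markers).

Gene expression is simulated as negative-binomial counts whose log-scale
latent trait carries an additive causal-marker effect, a polygenic term
Z u with iid normal marker effects, and Gaussian noise; the three components
are rescaled so their realized variance fractions match the configured
narrow-sense heritability on the latent (log) scale, the scale on which the
downstream pipeline operates after the log-cpm transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CountMatrix, GenotypeData, MarkerStatus

__all__ = [
    "SimConfig",
    "GeneSpec",
    "PhenotypeSpec",
    "TruthTable",
    "FounderHaplotypes",
    "simulate_founder_haplotypes",
    "simulate_f2_cross",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_gaussian_traits",
    "default_architecture",
    "default_phenotypes",
    "simulate_dataset",
]

GENE_CLASSES = ("null", "local", "distant", "hotspot-target")


@dataclass
class GeneSpec:
    """Planted architecture for one gene.

    ``causal_marker`` indexes the simulated marker map (marker id string);
    ``h2_true`` is the narrow-sense heritability of the latent log-scale trait.
    """
    gene: str
    gene_class: str
    causal_marker: str | None
    h2_true: float
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def validate(self):
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if not (0.0 <= self.h2_true <= 1.0):
            raise ValueError("h2_true must be in [0, 1]")
        if self.gene_class == "null" and self.h2_true > 0:
            raise ValueError(f"null gene {self.gene} cannot have h2_true > 0")
        if self.gene_class != "null" and self.causal_marker is None:
            raise ValueError(f"gene {self.gene} of class {self.gene_class} needs a causal marker")


@dataclass
class PhenotypeSpec:
    name: str
    causal_marker: str | None = None
    causal_var_frac: float = 0.0     # fraction of phenotypic variance from the marker
    poly_var_frac: float = 0.2      # polygenic fraction
    sex_effect: float = 0.0          # additive shift for sex == 1, in sd units
    shared_gene: str | None = None   # gene whose causal marker this phenotype shares


@dataclass
class SimConfig:
    seed: int = 0
    n_founder_sires: int = 4
    n_founder_dams: int = 15
    n_f1: int = 56
    n_f2: int = 200
    n_chrom: int = 5
    markers_per_chrom: int = 200
    chrom_length_bp: int = 100_000_000
    genetic_length_cM: float = 100.0
    founder_divergence: float = 0.3
    n_genes: int = 300
    architecture: list[GeneSpec] = field(default_factory=list)
    phenotypes: list[PhenotypeSpec] = field(default_factory=list)
    library_size_mean: float = 3e5
    dispersion: float = 0.01
    depth_sd: float = 0.15           # lognormal sd of per-sample sequencing depth
    latent_sd: float = 0.5           # total sd of the latent log-expression trait
    causal_var_frac: float = 0.7     # share of genetic variance at the causal marker
    two_tail_selection: bool = False # optional extreme-sampling scheme

    def __post_init__(self):
        for name in ("n_founder_sires", "n_founder_dams", "n_f1", "n_f2",
                     "n_chrom", "markers_per_chrom", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.founder_divergence <= 1.0):
            raise ValueError("founder_divergence must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        hotspot = {g.causal_marker for g in self.architecture
                   if g.gene_class == "hotspot-target"}
        if len(hotspot) > 1:
            raise ValueError("all hotspot-target genes must share one hotspot marker")
        for g in self.architecture:
            g.validate()


@dataclass
class TruthTable:
    genes: pd.DataFrame          # gene, class, causal_marker, h2_true, chrom, start, end
    phenotypes: pd.DataFrame     # phenotype, causal_marker, causal_var_frac, sex_effect
    pairs: pd.DataFrame          # gene, phenotype, shared_causal


@dataclass
class FounderHaplotypes:
    line_a: np.ndarray           # haplotypes x markers (0/1)
    line_b: np.ndarray
    map: pd.DataFrame            # marker, chrom, pos, cm


def _marker_map(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for c in range(cfg.n_chrom):
        m = cfg.markers_per_chrom
        pos = np.linspace(cfg.chrom_length_bp / (m + 1),
                          cfg.chrom_length_bp * m / (m + 1), m).astype(np.int64)
        cm = pos / cfg.chrom_length_bp * cfg.genetic_length_cM
        for j in range(m):
            rows.append((f"M{c + 1}_{j + 1}", f"chr{c + 1}", int(pos[j]), float(cm[j])))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "cm"])


def simulate_founder_haplotypes(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Two line-specific haplotype pools.

    A configured fraction of markers is fixed for alternate alleles between
    the lines (allele 1 in line A, allele 0 in line B); the remainder segregate
    at a shared frequency drawn uniformly from (0.1, 0.9).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mp = _marker_map(cfg)
    m = len(mp)
    n_div = int(round(cfg.founder_divergence * m))
    div_idx = rng.choice(m, size=n_div, replace=False) if n_div else np.array([], dtype=int)
    shared_freq = rng.uniform(0.1, 0.9, size=m)
    ha = (rng.random((2 * cfg.n_founder_sires, m)) < shared_freq).astype(np.int8)
    hb = (rng.random((2 * cfg.n_founder_dams, m)) < shared_freq).astype(np.int8)
    ha[:, div_idx] = 1
    hb[:, div_idx] = 0
    mp = mp.copy()
    mp["fixed_diff"] = False
    mp.loc[div_idx, "fixed_diff"] = True
    return FounderHaplotypes(line_a=ha, line_b=hb, map=mp)


def _meiosis(hap_pair, origin_pair, cm_chrom, rng):
    """One gamete from a parent's two haplotypes (Haldane crossovers)."""
    L = cm_chrom[-1] / 100.0 if len(cm_chrom) else 0.0
    n_x = rng.poisson(L)
    strand0 = rng.integers(0, 2)
    if n_x == 0:
        return hap_pair[strand0].copy(), origin_pair[strand0].copy()
    xpos = np.sort(rng.uniform(0.0, cm_chrom[-1], size=n_x))
    strand = (strand0 + np.searchsorted(xpos, cm_chrom, side="left")) % 2
    idx = np.arange(len(cm_chrom))
    return hap_pair[strand, idx], origin_pair[strand, idx]


def _gamete(haps, origins, chrom_slices, cms, rng):
    alle = np.empty(haps.shape[1], dtype=np.int8)
    orig = np.empty(haps.shape[1], dtype=np.int8)
    for sl, cm in zip(chrom_slices, cms):
        a, o = _meiosis(haps[:, sl], origins[:, sl], cm, rng)
        alle[sl], orig[sl] = a, o
    return alle, orig


def simulate_f2_cross(founders: FounderHaplotypes, cfg: SimConfig,
                      rng: np.random.Generator | None = None) -> GenotypeData:
    """Breed F1 then F2 animals by meiosis with Poisson (Haldane) crossovers.

    Returns dosages for the F2 cohort over all simulated markers (status
    'kept' everywhere; filtering is a downstream step) plus per-haplotype
    founder-line origin tracks for diagnostics.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    mp = founders.map
    if cfg.genetic_length_cM <= 0 and cfg.markers_per_chrom > 1:
        raise ValueError("zero genetic length with more than one marker")
    chrom_slices, cms = [], []
    for _, idx in mp.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        chrom_slices.append(slice(idx[0], idx[-1] + 1))
        cms.append(mp["cm"].to_numpy()[idx])

    m = len(mp)
    ha, hb = founders.line_a, founders.line_b

    # F1: one gamete from a random line-A founder, one from a random line-B founder.
    f1_h = np.empty((cfg.n_f1, 2, m), dtype=np.int8)
    f1_o = np.empty((cfg.n_f1, 2, m), dtype=np.int8)
    for i in range(cfg.n_f1):
        s = rng.integers(cfg.n_founder_sires)
        d = rng.integers(cfg.n_founder_dams)
        f1_h[i, 0], _ = _gamete(ha[2 * s:2 * s + 2], np.zeros((2, m), np.int8),
                                chrom_slices, cms, rng)
        f1_h[i, 1], _ = _gamete(hb[2 * d:2 * d + 2], np.ones((2, m), np.int8),
                                chrom_slices, cms, rng)
        f1_o[i, 0], f1_o[i, 1] = 0, 1

    # F2: two gametes from two distinct random F1 parents.
    M = np.empty((cfg.n_f2, m), dtype=np.int8)
    origin = np.empty((cfg.n_f2, 2, m), dtype=np.int8)
    for i in range(cfg.n_f2):
        pa, pb = rng.choice(cfg.n_f1, size=2, replace=False)
        g1, o1 = _gamete(f1_h[pa], f1_o[pa], chrom_slices, cms, rng)
        g2, o2 = _gamete(f1_h[pb], f1_o[pb], chrom_slices, cms, rng)
        M[i] = g1 + g2
        origin[i, 0], origin[i, 1] = o1, o2

    mp_out = mp[["marker", "chrom", "pos"]].copy()
    mp_out["status"] = MarkerStatus.KEPT
    mp_out["cm"] = mp["cm"].to_numpy()
    freq = M.mean(axis=0) / 2.0
    return GenotypeData(M=M.astype(float), p=freq, map=mp_out,
                        animal_ids=[f"F2_{i + 1}" for i in range(cfg.n_f2)],
                        line_origin=origin)


# -- planted architectures ----------------------------------------------------

def _pick_causal_markers(marker_map, rng, n, min_maf_proxy=None, spacing=5):
    """Sample well-spread marker ids, preferring line-divergent markers
    (MAF ~ 0.5 in the F2) so planted signals are detectable."""
    mp = marker_map
    pool = mp.index[mp["fixed_diff"]] if "fixed_diff" in mp else mp.index
    pool = np.asarray(pool)
    if pool.size < n:
        pool = np.asarray(mp.index)
    chosen = rng.choice(pool, size=n, replace=pool.size < n)
    return [mp.loc[i, "marker"] for i in chosen]


def default_architecture(marker_map: pd.DataFrame, n_genes: int,
                         rng: np.random.Generator,
                         frac_local: float = 0.2, frac_distant: float = 0.1,
                         n_hotspot_targets: int = 12,
                         h2_range=(0.3, 0.6), gene_length: int = 20_000,
                         chrom_length_bp: int = 100_000_000) -> list[GeneSpec]:
    """Study-condition gene architecture: a majority of null genes, local and
    distant regulated genes, and one hotspot marker driving 12 target genes."""
    n_local = int(round(frac_local * n_genes))
    n_distant = int(round(frac_distant * n_genes))
    if n_local + n_distant + n_hotspot_targets > n_genes:
        # tiny runs: drop the hotspot block rather than fail
        n_hotspot_targets = 0
    n_signal = n_local + n_distant + n_hotspot_targets
    if n_signal > n_genes:
        raise ValueError("architecture fractions exceed the gene budget")
    chroms = list(marker_map["chrom"].drop_duplicates())
    markers = _pick_causal_markers(marker_map, rng, n_local + n_distant + 1)
    hotspot = markers[-1]
    hs_row = marker_map[marker_map["marker"] == hotspot].iloc[0]
    specs: list[GeneSpec] = []
    k = 0

    def random_span(chrom):
        start = int(rng.integers(1, chrom_length_bp - gene_length))
        return chrom, start, start + gene_length

    for i in range(n_local):
        mk = markers[k]; k += 1
        row = marker_map[marker_map["marker"] == mk].iloc[0]
        offset = int(rng.integers(-200_000, 200_000))
        start = max(1, int(row["pos"]) + offset)
        specs.append(GeneSpec(f"G_local_{i + 1}", "local", mk,
                              float(rng.uniform(*h2_range)),
                              row["chrom"], start, start + gene_length))
    for i in range(n_distant):
        mk = markers[k]; k += 1
        row = marker_map[marker_map["marker"] == mk].iloc[0]
        other = rng.choice([c for c in chroms if c != row["chrom"]])
        specs.append(GeneSpec(f"G_distant_{i + 1}", "distant", mk,
                              float(rng.uniform(*h2_range)),
                              *random_span(other)))
    for i in range(n_hotspot_targets):
        other = rng.choice([c for c in chroms if c != hs_row["chrom"]])
        specs.append(GeneSpec(f"G_hub_{i + 1}", "hotspot-target", hotspot,
                              float(rng.uniform(*h2_range)),
                              *random_span(other)))
    for i in range(n_genes - n_signal):
        specs.append(GeneSpec(f"G_null_{i + 1}", "null", None, 0.0,
                              *random_span(rng.choice(chroms))))
    return specs


def default_phenotypes(architecture: list[GeneSpec],
                       rng: np.random.Generator | None = None) -> list[PhenotypeSpec]:
    """Phenotype battery: two traits sharing a causal marker with a gene
    (driving co-localization truth), one with its own QTL, two null traits."""
    shared = [g for g in architecture if g.gene_class in ("local", "distant")][:2]
    specs = []
    for i, g in enumerate(shared):
        specs.append(PhenotypeSpec(f"P_shared_{i + 1}", causal_marker=g.causal_marker,
                                   causal_var_frac=0.15, poly_var_frac=0.2,
                                   sex_effect=0.2, shared_gene=g.gene))
    specs.append(PhenotypeSpec("P_own_qtl", causal_marker=None,
                               causal_var_frac=0.15, poly_var_frac=0.2,
                               sex_effect=0.0))
    specs.append(PhenotypeSpec("P_null_1", poly_var_frac=0.2, sex_effect=0.3))
    specs.append(PhenotypeSpec("P_null_2", poly_var_frac=0.0, sex_effect=0.0))
    return specs


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if target_var <= 0 or sd == 0:
        return np.zeros_like(x)
    return x * (np.sqrt(target_var) / sd)


def _centered_dosage_matrix(geno: GenotypeData) -> np.ndarray:
    Z0 = geno.M - geno.M.mean(axis=0)
    sd = Z0.std(axis=0)
    sd[sd == 0] = 1.0
    return Z0 / sd


def simulate_expression(geno: GenotypeData, cfg: SimConfig,
                        rng: np.random.Generator | None = None):
    """Negative-binomial counts with planted additive genetic signal.

    For each gene the latent log-scale trait is the sum of a causal-marker
    effect, a polygenic term Z u, and Gaussian noise, rescaled so the realized
    variance fractions equal h2_true * causal_var_frac, h2_true * (1 -
    causal_var_frac) and (1 - h2_true) of latent_sd^2.  Counts are drawn
    NB(mean = libsize_i * base_g * exp(latent)) with gamma-Poisson dispersion.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    specs = cfg.architecture
    if not specs:
        raise ValueError("SimConfig.architecture is empty")
    marker_index = {m: j for j, m in enumerate(geno.map["marker"])}
    for g in specs:
        g.validate()
        if g.causal_marker is not None and g.causal_marker not in marker_index:
            raise ValueError(f"causal marker {g.causal_marker} not in the map")

    n = geno.M.shape[0]
    Z0 = _centered_dosage_matrix(geno)
    var_L = cfg.latent_sd**2
    depth = np.exp(rng.normal(0.0, cfg.depth_sd, size=n)) if cfg.depth_sd > 0 \
        else np.ones(n)
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=len(specs))
    base = rel / rel.sum() * cfg.library_size_mean

    counts = np.empty((len(specs), n), dtype=np.int64)
    rows = []
    for gi, g in enumerate(specs):
        h2 = g.h2_true
        cf = cfg.causal_var_frac if g.causal_marker is not None else 0.0
        latent = np.zeros(n)
        if g.causal_marker is not None and h2 > 0:
            dos = geno.M[:, marker_index[g.causal_marker]]
            if dos.std() == 0:
                raise ValueError(f"causal marker {g.causal_marker} is monomorphic")
            latent += _scale_to_var(dos, h2 * cf * var_L)
        if h2 > 0 and cf < 1.0:
            u = rng.normal(size=Z0.shape[1])
            latent += _scale_to_var(Z0 @ u, h2 * (1.0 - cf) * var_L)
        latent += _scale_to_var(rng.normal(size=n), (1.0 - h2) * var_L)
        mu = base[gi] * depth * np.exp(latent)
        if cfg.dispersion > 0:
            lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
            counts[gi] = rng.poisson(lam)
        else:
            counts[gi] = rng.poisson(mu)
        rows.append((g.gene, g.gene_class, g.causal_marker, h2,
                     g.chrom, g.start, g.end))

    genes = pd.DataFrame(rows, columns=["gene", "class", "causal_marker",
                                        "h2_true", "chrom", "start", "end"])
    cm = CountMatrix(counts=counts,
                     genes=genes[["gene", "chrom", "start", "end"]].copy(),
                     samples=list(geno.animal_ids) or list(range(n)))
    return cm, genes


def simulate_phenotypes(geno: GenotypeData, cfg: SimConfig,
                        rng: np.random.Generator | None = None):
    """Phenotypes with a sex fixed effect, optional causal marker, polygenic
    term and Gaussian error; variance fractions match the spec of each trait."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    n = geno.M.shape[0]
    sex = rng.integers(0, 2, size=n)
    marker_index = {m: j for j, m in enumerate(geno.map["marker"])}
    Z0 = _centered_dosage_matrix(geno)
    data = {"animal": geno.animal_ids or list(range(n)), "sex": sex}
    rows, pairs = [], []
    for spec in cfg.phenotypes:
        mk = spec.causal_marker
        if mk is None and spec.causal_var_frac > 0:
            mk = _pick_causal_markers(geno.map, rng, 1)[0]
        if mk is not None and mk not in marker_index:
            raise ValueError(f"causal marker {mk} not in the map")
        err = 1.0 - spec.causal_var_frac - spec.poly_var_frac
        if err < 0:
            raise ValueError(f"variance fractions exceed 1 for {spec.name}")
        y = np.zeros(n)
        if mk is not None and spec.causal_var_frac > 0:
            y += _scale_to_var(geno.M[:, marker_index[mk]], spec.causal_var_frac)
        if spec.poly_var_frac > 0:
            y += _scale_to_var(Z0 @ rng.normal(size=Z0.shape[1]), spec.poly_var_frac)
        y += _scale_to_var(rng.normal(size=n), err)
        y += spec.sex_effect * sex
        data[spec.name] = y
        rows.append((spec.name, mk if spec.causal_var_frac > 0 else None,
                     spec.causal_var_frac, spec.sex_effect, spec.shared_gene))
        if spec.shared_gene is not None:
            pairs.append((spec.shared_gene, spec.name, True))
    phen = pd.DataFrame(data)
    truth_p = pd.DataFrame(rows, columns=["phenotype", "causal_marker",
                                          "causal_var_frac", "sex_effect",
                                          "shared_gene"])
    truth_pairs = pd.DataFrame(pairs, columns=["gene", "phenotype", "shared_causal"])
    return phen, truth_p, truth_pairs


def simulate_gaussian_traits(Z: np.ndarray, h2: float, n_traits: int,
                             rng: np.random.Generator):
    """Latent-scale polygenic traits y = Zu + e with realized variance split
    exactly (h2, 1-h2); used for variance-component recovery checks."""
    n, m = Z.shape
    out = np.empty((n_traits, n))
    for t in range(n_traits):
        g = _scale_to_var(Z @ rng.normal(size=m), h2)
        e = _scale_to_var(rng.normal(size=n), 1.0 - h2)
        out[t] = g + e
    return out


def simulate_dataset(cfg: SimConfig):
    """Full generator: founders -> F2 genotypes -> counts + phenotypes + truth.

    ``cfg`` is not mutated: a default architecture/phenotype battery is built
    on a copy when none is configured, so repeated calls with the same config
    and seed are bit-identical.
    """
    import dataclasses
    root = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(5)]
    founders = simulate_founder_haplotypes(cfg, rngs[0])
    scheme = None
    if cfg.two_tail_selection:
        # breed a double-size pool, keep the tails of a heritable selection
        # trait; the tail indicator becomes the 'scheme' fixed covariate
        pool_cfg = dataclasses.replace(cfg, n_f2=2 * cfg.n_f2)
        geno = simulate_f2_cross(founders, pool_cfg, rngs[1])
        sel_rng = rngs[4]
        Z0 = _centered_dosage_matrix(geno)
        sel = (_scale_to_var(Z0 @ sel_rng.normal(size=Z0.shape[1]), 0.4)
               + _scale_to_var(sel_rng.normal(size=2 * cfg.n_f2), 0.6))
        order = np.argsort(sel)
        half = cfg.n_f2 // 2
        idx = np.sort(np.concatenate([order[:half], order[-(cfg.n_f2 - half):]]))
        scheme = (sel[idx] > np.median(sel)).astype(int)
        geno = GenotypeData(M=geno.M[idx], p=geno.M[idx].mean(axis=0) / 2.0,
                            map=geno.map,
                            animal_ids=[geno.animal_ids[i] for i in idx],
                            line_origin=geno.line_origin[idx])
    else:
        geno = simulate_f2_cross(founders, cfg, rngs[1])
    # carry the fixed-diff flag for architecture building
    geno.map["fixed_diff"] = founders.map["fixed_diff"].to_numpy()
    arch = cfg.architecture or default_architecture(
        geno.map, cfg.n_genes, rngs[2], chrom_length_bp=cfg.chrom_length_bp)
    phens = cfg.phenotypes or default_phenotypes(arch)
    cfg = dataclasses.replace(cfg, architecture=arch, phenotypes=phens)
    counts, truth_genes = simulate_expression(geno, cfg, rngs[2])
    phen, truth_phen, truth_pairs = simulate_phenotypes(geno, cfg, rngs[3])
    if scheme is not None:
        phen.insert(2, "scheme", scheme)
    truth = TruthTable(genes=truth_genes, phenotypes=truth_phen, pairs=truth_pairs)
    return geno, counts, phen, truth
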