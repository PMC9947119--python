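"""Seeded synthetic fixtures for the two-cultivar, four-niche field design.

The generators emulate the statistical structure every downstream stage
assumes: a full-factorial sample grid over cultivar x treatment x replicate
x niche, alpha diversity that declines along the soil->root continuum
(nested per-niche retention of a shared soil pool), cultivar-enriched
biomarker taxa with known log-fold effects, modular correlation structure,
community pairs with a known assembly process, and grain-Cd measurements
linearly linked to planted biomarker abundances.

Abundances follow a log-normal latent mean plus multinomial read sampling,
which reproduces the sparse, overdispersed look of ASV tables without
modelling sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import NICHE_ORDER, CdTable, CommunityMatrix
from .errors import InvalidArgumentError, InvalidDesignError, SchemaError

CULTIVAR_LABELS = ("XS14", "YY17")
TREATMENT_LABELS = ("CK", "LM", "BC", "PM", "CMC")

ASSEMBLY_SCENARIOS = (
    "selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


@dataclass
class StudyDesign:
    """Factorial sampling design of the pot/field experiment.

    Defaults mirror a 2-cultivar x 5-treatment x 3-replicate x 4-niche grid
    (120 samples).  ``depth_mean`` is the expected per-sample read depth;
    per-sample depths are Poisson around it so rarefaction is non-trivial.
    """

    n_cultivars: int = 2
    n_treatments: int = 5
    n_replicates: int = 3
    niches: tuple[str, ...] = NICHE_ORDER
    n_taxa: int = 300
    depth_mean: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cultivars", "n_treatments", "n_replicates", "n_taxa"):
            if getattr(self, name) < 1:
                raise InvalidDesignError(f"{name} must be >= 1")
        if len(self.niches) < 1 or len(set(self.niches)) != len(self.niches):
            raise InvalidDesignError("niches must be a non-empty list of unique labels")
        if self.depth_mean < 1:
            raise InvalidDesignError("depth_mean must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_cultivars * self.n_treatments * self.n_replicates * len(self.niches)

    def cultivar_labels(self) -> list[str]:
        if self.n_cultivars == 2:
            return list(CULTIVAR_LABELS)
        return [f"cv{i + 1}" for i in range(self.n_cultivars)]

    def treatment_labels(self) -> list[str]:
        if self.n_treatments <= len(TREATMENT_LABELS):
            return list(TREATMENT_LABELS[: self.n_treatments])
        return [f"T{i + 1}" for i in range(self.n_treatments)]


@dataclass
class PlantedTruth:
    """Ground truth planted into generated communities.

    biomarker_taxa maps cultivar -> {taxon: log-fold enrichment in that
    cultivar}; niche_retention gives the fraction of the soil pool retained
    per niche (non-increasing along the continuum; filtering is nested, so
    each niche's taxon set is a subset of the previous one); cd_link maps
    taxa to linear coefficients on grain Cd (per standardized abundance).
    """

    biomarker_taxa: dict[str, dict[str, float]] = field(default_factory=dict)
    module_assignments: dict[str, int] = field(default_factory=dict)
    assembly_scenario: str = "drift"
    niche_retention: tuple[float, ...] = (1.0, 0.6, 0.4, 0.2)
    cd_link: dict[str, float] = field(default_factory=dict)
    cd_intercept: float = 0.5
    cd_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for cv, taxa in self.biomarker_taxa.items():
            for t, eff in taxa.items():
                if not np.isfinite(eff):
                    raise InvalidDesignError(f"non-finite effect for {t} in {cv}")
        r = np.asarray(self.niche_retention, dtype=float)
        if np.any(r <= 0) or np.any(r > 1):
            raise InvalidDesignError("retention fractions must be in (0, 1]")
        if np.any(np.diff(r) > 0):
            raise InvalidDesignError("retention must be non-increasing along the continuum")
        if self.assembly_scenario not in ASSEMBLY_SCENARIOS:
            raise InvalidArgumentError(f"unknown assembly scenario {self.assembly_scenario!r}")

    def all_biomarkers(self) -> set[str]:
        out: set[str] = set()
        for taxa in self.biomarker_taxa.values():
            out.update(taxa)
        return out


def taxon_labels(n_taxa: int) -> list[str]:
    return [f"ASV{i + 1:04d}" for i in range(n_taxa)]


def default_truth(
    design: StudyDesign,
    n_biomarkers: int = 5,
    effect: float = 2.0,
    n_modules: int = 6,
    cd_coefficient: float = 0.15,
) -> PlantedTruth:
    """Standard planted truth for a design: ``n_biomarkers`` enriched taxa per
    cultivar at log-fold ``effect``, block module structure, and a positive Cd
    link on the first cultivar's biomarkers."""
    rng = np.random.default_rng(design.seed + 101)
    taxa = taxon_labels(design.n_taxa)
    cultivars = design.cultivar_labels()
    picks = rng.choice(design.n_taxa, size=n_biomarkers * len(cultivars), replace=False)
    biomarkers = {
        cv: {taxa[j]: effect for j in picks[i * n_biomarkers : (i + 1) * n_biomarkers]}
        for i, cv in enumerate(cultivars)
    }
    modules = {t: int(i % n_modules) for i, t in enumerate(taxa)}
    retention = tuple(np.linspace(1.0, 0.25, len(design.niches)))
    cd_link = {t: cd_coefficient for t in biomarkers[cultivars[0]]}
    return PlantedTruth(
        biomarker_taxa=biomarkers,
        module_assignments=modules,
        niche_retention=retention,
        cd_link=cd_link,
    )


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def generate_phylogeny(n_taxa: int, seed: int) -> TreeNode:
    """Random coalescent phylogeny over ``n_taxa`` uniquely labelled tips.

    Lineages coalesce pairwise at exponential waiting times with the standard
    rate k(k-1)/2 for k extant lineages; each resulting branch is then jittered
    by a log-normal rate factor so the tree is not exactly ultrametric and
    cophenetic distances are non-degenerate.  Deterministic given the seed.
    """
    if n_taxa < 3:
        raise InvalidDesignError("a phylogeny needs at least 3 tips")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=name) for name in taxon_labels(n_taxa)]
    heights = [0.0] * n_taxa
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(scale=2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        ha, hb = heights[i], heights[j]
        a.length = round((t - ha) * rng.lognormal(mean=0.0, sigma=0.25), 10)
        b.length = round((t - hb) * rng.lognormal(mean=0.0, sigma=0.25), 10)
        parent = TreeNode(children=[a, b])
        # replace j first so index i stays valid
        nodes.pop(j)
        heights.pop(j)
        nodes[i] = parent
        heights[i] = t
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# factorial community tables
# ---------------------------------------------------------------------------

def _latent_pool(rng: np.random.Generator, n_taxa: int, sigma_base: float = 1.5) -> np.ndarray:
    return rng.normal(0.0, sigma_base, size=n_taxa)


def generate_communities(
    design: StudyDesign,
    truth: PlantedTruth,
    sigma_module: float = 0.8,
    sigma_noise: float = 0.5,
    min_depth: int = 50,
) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Simulate the full factorial count table plus aligned metadata.

    Per sample, taxon log-abundances are base pool means + cultivar biomarker
    effects + a shared module-level random effect + taxon noise; the niche
    applies a nested retention mask; reads are a multinomial draw at a
    Poisson per-sample depth (floored at ``min_depth``).
    """
    taxa = np.array(taxon_labels(design.n_taxa))
    taxon_set = set(taxa)
    unknown = (truth.all_biomarkers() | set(truth.cd_link)) - taxon_set
    if unknown:
        raise SchemaError(f"planted taxa absent from design taxon set: {sorted(unknown)}")
    if len(truth.niche_retention) != len(design.niches):
        raise SchemaError("niche_retention length must match design.niches")

    rng = np.random.default_rng(design.seed)
    mu = _latent_pool(rng, design.n_taxa)
    retention_u = rng.uniform(size=design.n_taxa)

    biomarker_idx = {t: i for i, t in enumerate(taxa)}
    forced = np.zeros(design.n_taxa, dtype=bool)
    for t in truth.all_biomarkers():
        forced[biomarker_idx[t]] = True

    module_of = np.array([truth.module_assignments.get(t, 0) for t in taxa])
    n_modules = int(module_of.max()) + 1

    effect = {cv: np.zeros(design.n_taxa) for cv in design.cultivar_labels()}
    for cv, taxmap in truth.biomarker_taxa.items():
        if cv not in effect:
            raise SchemaError(f"unknown cultivar in truth: {cv!r}")
        for t, e in taxmap.items():
            effect[cv][biomarker_idx[t]] = e

    rows, meta_rows = [], []
    for cv in design.cultivar_labels():
        for tr in design.treatment_labels():
            for rep in range(1, design.n_replicates + 1):
                for k, niche in enumerate(design.niches):
                    present = (retention_u <= truth.niche_retention[k]) | forced
                    z_mod = rng.normal(0.0, 1.0, size=n_modules)
                    latent = (
                        mu
                        + effect[cv]
                        + sigma_module * z_mod[module_of]
                        + rng.normal(0.0, sigma_noise, size=design.n_taxa)
                    )
                    w = np.where(present, np.exp(latent), 0.0)
                    p = w / w.sum()
                    depth = max(int(rng.poisson(design.depth_mean)), min_depth)
                    counts = rng.multinomial(depth, p)
                    sample_id = f"{cv}_{tr}_{niche}_r{rep}"
                    rows.append((sample_id, counts))
                    meta_rows.append((sample_id, cv, niche, tr, rep))

    counts = pd.DataFrame(
        np.vstack([c for _, c in rows]),
        index=[s for s, _ in rows],
        columns=taxa,
    )
    matrix = CommunityMatrix(counts=counts).drop_empty_taxa()
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "cultivar", "niche", "treatment", "replicate"]
    )
    return matrix, metadata


# ---------------------------------------------------------------------------
# assembly-scenario community pairs
# ---------------------------------------------------------------------------

def _brownian_trait(tree: TreeNode, rng: np.random.Generator, taxa: list[str]) -> np.ndarray:
    """Brownian-motion trait along the tree; standardized across tips."""
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        bl = node.length if node.length is not None else 0.0
        values[id(node)] = parent_val + rng.normal(0.0, np.sqrt(max(bl, 1e-12)))
    tip_vals = {t.name: values[id(t)] for t in tree.tips()}
    trait = np.array([tip_vals[t] for t in taxa])
    return (trait - trait.mean()) / trait.std()


def generate_assembly_pair_set(
    scenario: str,
    n_pairs: int,
    seed: int,
    n_taxa: int = 150,
    depth: int = 1200,
    drift_concentration: float = 1000.0,
) -> tuple[CommunityMatrix, TreeNode]:
    """Community pairs whose true generating process is known.

    selection: both members filtered from the pool by a phylogenetically
    conserved (Brownian) trait under two contrasting environmental optima.
    drift: independent draws from one shared pool with Dirichlet-multinomial
    demographic heterogeneity (``drift_concentration`` controls how far each
    community's composition drifts from the pool).
    dispersal_limitation: the pair draws from disjoint random halves of the
    pool (no phylogenetic signal, depressed overlap).
    homogenizing_dispersal: the second member resamples the first (overlap
    far above the pool expectation).

    Rows are named ``pair####_a`` / ``pair####_b``.
    """
    if scenario not in ASSEMBLY_SCENARIOS:
        raise InvalidArgumentError(
            f"unknown scenario {scenario!r}; expected one of {ASSEMBLY_SCENARIOS}"
        )
    if n_pairs < 1:
        raise InvalidArgumentError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    tree = generate_phylogeny(n_taxa, seed)
    taxa = taxon_labels(n_taxa)
    pool_logit = _latent_pool(rng, n_taxa, sigma_base=1.2)
    pool_p = np.exp(pool_logit)
    pool_p /= pool_p.sum()

    trait = _brownian_trait(tree, rng, taxa) if scenario == "selection" else None

    rows: list[np.ndarray] = []
    names: list[str] = []
    for i in range(n_pairs):
        if scenario == "drift":
            a = rng.multinomial(depth, rng.dirichlet(drift_concentration * pool_p))
            b = rng.multinomial(depth, rng.dirichlet(drift_concentration * pool_p))
        elif scenario == "selection":
            wa = pool_p * np.exp(-((trait - (-1.2)) ** 2) / (2 * 0.35**2))
            wb = pool_p * np.exp(-((trait - 1.2) ** 2) / (2 * 0.35**2))
            a = rng.multinomial(depth, wa / wa.sum())
            b = rng.multinomial(depth, wb / wb.sum())
        elif scenario == "dispersal_limitation":
            perm = rng.permutation(n_taxa)
            half = n_taxa // 2
            mask_a = np.zeros(n_taxa, dtype=bool)
            mask_a[perm[:half]] = True
            wa = np.where(mask_a, pool_p, 0.0)
            wb = np.where(~mask_a, pool_p, 0.0)
            a = rng.multinomial(depth, wa / wa.sum())
            b = rng.multinomial(depth, wb / wb.sum())
        else:  # homogenizing_dispersal
            a = rng.multinomial(depth, pool_p)
            b = rng.multinomial(depth, a / a.sum())
        rows += [a, b]
        names += [f"pair{i + 1:04d}_a", f"pair{i + 1:04d}_b"]

    counts = pd.DataFrame(np.vstack(rows), index=names, columns=taxa)
    return CommunityMatrix(counts=counts), tree


def pair_index(matrix: CommunityMatrix) -> list[tuple[str, str]]:
    """Recover the (a, b) sample-id pairs from a pair-set matrix."""
    ids = matrix.sample_ids
    return [(ids[i], ids[i + 1]) for i in range(0, len(ids), 2)]


def generate_nested_niche_set(
    seed: int,
    niches: tuple[str, ...] = NICHE_ORDER,
    retention: tuple[float, ...] = (1.0, 0.6, 0.4, 0.2),
    n_taxa: int = 150,
    n_per_niche: int = 6,
    depth: int = 2000,
    jitter_concentration: float = 500.0,
) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Niche communities that are successive filtered subsets of one soil pool.

    Each niche's expected profile is the pool restricted to a nested taxon
    subset (uniform scores against the non-increasing retention fractions)
    and renormalized; samples add mild Dirichlet compositional jitter.  This
    is the cleanest fixture for source-apportionment along the continuum:
    every niche's closest match among candidate sources is the adjacent
    upstream niche.
    """
    if len(retention) != len(niches):
        raise InvalidDesignError("retention length must match niches")
    rng = np.random.default_rng(seed)
    taxa = taxon_labels(n_taxa)
    pool = np.exp(_latent_pool(rng, n_taxa, sigma_base=1.2))
    u = rng.uniform(size=n_taxa)
    rows, meta_rows = [], []
    for k, niche in enumerate(niches):
        mask = u <= retention[k]
        if not mask.any():
            raise InvalidDesignError(f"retention {retention[k]} leaves niche {niche!r} empty")
        profile = np.where(mask, pool, 0.0)
        profile = profile / profile.sum()
        conc = np.where(profile > 0, jitter_concentration * profile, 0.0)
        for r in range(n_per_niche):
            p = np.zeros(n_taxa)
            p[mask] = rng.dirichlet(conc[mask])
            sid = f"{niche}_s{r + 1}"
            rows.append(rng.multinomial(depth, p))
            meta_rows.append((sid, "XS14", niche, "CK", r + 1))
    counts = pd.DataFrame(
        np.vstack(rows), index=[m[0] for m in meta_rows], columns=taxa
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "cultivar", "niche", "treatment", "replicate"]
    )
    return CommunityMatrix(counts=counts).drop_empty_taxa(), metadata


# ---------------------------------------------------------------------------
# cadmium measurements
# ---------------------------------------------------------------------------

def generate_cd_measurements(
    design: StudyDesign,
    truth: PlantedTruth,
    communities: CommunityMatrix,
    metadata: pd.DataFrame,
    reference_niche: str = "rhizosphere",
) -> CdTable:
    """Per-plot grain Cd and soil Cd (mg/kg).

    Grain Cd is a linear function of the planted biomarkers' standardized
    relative abundances in the plot's ``reference_niche`` sample, plus
    Gaussian noise; all outputs are strictly positive (floored at 1e-3).
    """
    missing = set(truth.cd_link) - set(communities.taxon_ids)
    if missing:
        raise SchemaError(f"cd_link taxa absent from community table: {sorted(missing)}")
    if reference_niche not in set(metadata["niche"]):
        raise SchemaError(f"reference niche {reference_niche!r} not in metadata")

    rng = np.random.default_rng(design.seed + 7919)
    rel = communities.relative_abundance()
    ref = metadata[metadata["niche"] == reference_niche]

    plots = ref[["cultivar", "treatment", "replicate"]].drop_duplicates()
    link_taxa = sorted(truth.cd_link)
    # standardized biomarker abundance per plot
    abund = np.zeros((len(plots), len(link_taxa)))
    for r, (_, plot) in enumerate(plots.iterrows()):
        sel = ref[
            (ref["cultivar"] == plot["cultivar"])
            & (ref["treatment"] == plot["treatment"])
            & (ref["replicate"] == plot["replicate"])
        ]["sample_id"]
        abund[r] = rel.loc[sel, link_taxa].to_numpy().mean(axis=0) if len(sel) else 0.0
    sd = abund.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (abund - abund.mean(axis=0)) / sd

    coefs = np.array([truth.cd_link[t] for t in link_taxa])
    grain = truth.cd_intercept + z @ coefs + rng.normal(0.0, truth.cd_noise_sd, size=len(plots))
    grain = np.maximum(grain, 1e-3)
    soil_total = rng.lognormal(mean=np.log(0.6), sigma=0.15, size=len(plots))
    available = soil_total * rng.uniform(0.3, 0.6, size=len(plots))

    table = plots.reset_index(drop=True).copy()
    table["grain_cd"] = grain
    table["soil_total_cd"] = soil_total
    table["soil_available_cd"] = available
    return CdTable(table=table)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixtures(outdir, design: StudyDesign, truth: PlantedTruth | None = None) -> dict[str, str]:
    """Generate and write the full fixture bundle (TSV + newick) to ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    if truth is None:
        truth = default_truth(design)
    matrix, metadata = generate_communities(design, truth)
    tree = generate_phylogeny(design.n_taxa, design.seed)
    cd = generate_cd_measurements(design, truth, matrix, metadata)

    paths = {
        "table": os.path.join(outdir, "asv_table.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "tree": os.path.join(outdir, "tree.nwk"),
        "cd": os.path.join(outdir, "cd_measurements.tsv"),
    }
    matrix.to_tsv(paths["table"])
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    tree.write(paths["tree"])
    cd.to_tsv(paths["cd"])
    return paths
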