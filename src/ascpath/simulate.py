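"""Synthetic division-structured B-cell differentiation data.

Emulates the statistical structure of an LPS-driven B-cell response profiled
across ~8 cell divisions: total mRNA content grows multiplicatively with
division, lineages bifurcate after a branch-point division into an
ASC-destined branch (plasma-cell program up, Sell-analog down, OXPHOS/MYC
modules up) and a non-ASC branch (Sell-analog retained, inflammatory module
up), and terminal ASCs sub-split on an ER-chaperone module.  UMI counts are
negative-binomial with per-cell lognormal capture efficiency shared by
biological genes and a constant ERCC-like spike pool, so spike-based
molecules-per-cell normalization is recoverable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "ReferencePanel",
    "simulate_experiment",
    "simulate_bulk_reference",
    "simulate_regulons",
    "PANEL_LABELS",
    "PANEL_CELL_TYPES",
]

#: division labels of the bulk reference panel and their cell-type annotation
PANEL_LABELS = ("0", "1", "3", "5", "8-", "8+")
PANEL_CELL_TYPES = {
    "0": "nB",
    "1": "actB",
    "3": "actB",
    "5": "actB",
    "8-": "actB",
    "8+": "ASC",
}

#: recognizable marker aliases placed at the head of each module
_MODULE_ALIASES = {
    "asc": ["Prdm1_like", "Xbp1_like", "Irf4_like", "Sdc1_like"],
    "bcell": ["Sell_like", "Ms4a1_like"],
    "oxphos": ["Myc_like", "Ndufa_like"],
    "inflam": ["Nfkbia_like", "Il6_like"],
    "er": ["Hspa5_like", "Atf6_like"],
    "naive": ["Bach2_like", "Klf2_like"],
    "division": ["Mki67_like", "Ccnb1_like"],
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults encode the study conditions the analysis assumes: a 0-8 division
    ladder with triangular occupancy peaking mid-ladder, a bifurcation at
    division 3 with half of post-branch cells ASC-destined, ~30% of terminal
    ASCs in the ER-stress sub-state, 1.3-fold total-mRNA growth per division,
    and moderately overdispersed counts with 30% capture-efficiency CV.
    """

    n_cells: int = 2000
    n_genes: int = 1500
    n_spikes: int = 30
    divisions: tuple[int, ...] = tuple(range(9))
    branch_point_division: int = 3
    asc_fraction: float = 0.5
    er_stress_fraction: float = 0.3
    mrna_scale_per_division: float = 1.3
    module_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "asc": 60,
            "bcell": 30,
            "oxphos": 80,
            "inflam": 60,
            "er": 40,
            "naive": 40,
            "division": 60,
        }
    )
    nb_dispersion: float = 0.1  # NB variance = m + dispersion * m^2
    libsize_cv: float = 0.3
    bulk_replicates: int = 3
    bulk_noise_sd: float = 0.15  # lognormal sdlog of bulk replicate noise
    division_weights: tuple[float, ...] | None = None
    base_total_umi: float = 3000.0  # expected division-0 library size
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_genes < 0 or self.n_spikes < 0:
            raise ValueError("n_cells, n_genes and n_spikes must be >= 0")
        if not 0.0 <= self.asc_fraction <= 1.0:
            raise ValueError("asc_fraction must lie in [0, 1]")
        if not 0.0 <= self.er_stress_fraction <= 1.0:
            raise ValueError("er_stress_fraction must lie in [0, 1]")
        if self.mrna_scale_per_division < 1.0:
            raise ValueError("mrna_scale_per_division must be >= 1")
        if sum(self.module_sizes.values()) > self.n_genes:
            raise ValueError("sum of module_sizes exceeds n_genes")
        if self.bulk_replicates < 1:
            raise ValueError("bulk_replicates must be >= 1")
        if self.division_weights is not None and len(self.division_weights) != len(
            self.divisions
        ):
            raise ValueError("division_weights must match divisions in length")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class ReferencePanel:
    """Labeled bulk replicate profiles used as a KNN training set.

    ``matrix`` is genes (spike rows included, 'ERCC-' prefixed) x replicate
    columns; ``labels`` maps each replicate column to its division label and
    ``cell_types`` maps division labels to nB/actB/ASC.
    """

    matrix: pd.DataFrame
    labels: pd.Series  # replicate column -> division label
    cell_types: dict[str, str] = field(default_factory=lambda: dict(PANEL_CELL_TYPES))

    @property
    def replicates_per_label(self) -> pd.Series:
        return self.labels.value_counts()


def _gene_names(config: SimulationConfig) -> tuple[pd.Index, pd.Series]:
    """Gene identifiers plus per-gene module membership."""
    names: list[str] = []
    modules: list[str] = []
    for mod, size in config.module_sizes.items():
        aliases = _MODULE_ALIASES.get(mod, [])
        for i in range(size):
            if i < len(aliases):
                names.append(aliases[i])
            else:
                names.append(f"{mod.upper()}_{i:03d}")
            modules.append(mod)
    n_bg = config.n_genes - len(names)
    names.extend(f"Gene_{i:05d}" for i in range(n_bg))
    modules.extend("none" for _ in range(n_bg))
    return pd.Index(names, name="gene"), pd.Series(modules, index=names, name="module")


def _base_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Baseline expected expression per gene (arbitrary units, later scaled)."""
    mu = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    return mu


def _division_grid(config: SimulationConfig) -> np.ndarray:
    return np.asarray(sorted(config.divisions), dtype=int)


def _occupancy(config: SimulationConfig) -> np.ndarray:
    divs = _division_grid(config)
    if config.division_weights is not None:
        w = np.asarray(config.division_weights, dtype=float)
    else:
        # dye-dilution-like occupancy: a retained undivided pool plus a
        # triangular bulk peaking at division 5 (72 h LPS response)
        w = np.maximum(1.0, 6.0 - np.abs(divs - 5.0))
        w[divs == 0] = 3.0
    return w / w.sum()


# multiplicative effect sizes at full ramp (r = 1 / final division)
_ACTIVATION_UP = 2.0  # shared OXPHOS/MYC metabolic scaling of activated cells
_DIVISION_UP = 16.0  # proliferation/biosynthesis program ramping with division on all branches
_NAIVE_DOWN = 4.0  # naive/resting program, high at division 0, decaying on all branches
_NB_STATE_BOOST = 1.5  # extra naive-module factor in undivided resting cells
_ASC_UP = 7.0
_OXPHOS_UP = 4.0  # extra OXPHOS/MYC gain on the ASC-destined branch
_INFLAM_UP = 8.0
_SELL_DOWN = 0.95  # fraction of Sell-analog expression lost at r = 1
_ASC_STATE_BOOST = 3.0  # extra ASC-module factor in the terminal ASC state
_ER_UP = 5.0


#: branch progression at the commitment division; fate choice is a discrete
#: switch (IRF4-high vs -low) followed by gradual maturation
_COMMITMENT_OFFSET = 0.15
_RAMP_EXPONENT = 2.0


def _ramp(division: int, config: SimulationConfig) -> float:
    """Branch progression in [0, 1]; jumps at the branch point, then ramps."""
    bp = config.branch_point_division
    d_max = int(max(config.divisions))
    if division < bp:
        return 0.0
    if d_max == bp:
        return 1.0
    frac = ((division - bp) / (d_max - bp)) ** _RAMP_EXPONENT
    return _COMMITMENT_OFFSET + (1.0 - _COMMITMENT_OFFSET) * frac


def program_mean(
    base: np.ndarray,
    modules: pd.Series,
    division: int,
    branch: str,
    state: str,
    config: SimulationConfig,
) -> np.ndarray:
    """Expected per-cell expression (capture efficiency 1) of one program.

    The division-wise total-mRNA growth factor is applied here, so summing the
    returned vector tracks total mRNA content.
    """
    mod = modules.to_numpy()
    mu = base.copy()
    d_max = int(max(config.divisions))
    a = division / d_max if d_max > 0 else 0.0
    # metabolic activation ramps with division on every responding cell
    mu[mod == "oxphos"] *= 1.0 + _ACTIVATION_UP * a
    mu[mod == "division"] *= 1.0 + _DIVISION_UP * a
    mu[mod == "naive"] *= 1.0 + _NAIVE_DOWN * (1.0 - a)
    if state == "nB":
        mu[mod == "naive"] *= _NB_STATE_BOOST
    r = _ramp(division, config)
    if branch == "ASC-destined":
        mu[mod == "asc"] *= 1.0 + _ASC_UP * r
        mu[mod == "oxphos"] *= 1.0 + _OXPHOS_UP * r
        mu[mod == "bcell"] *= 1.0 - _SELL_DOWN * r
        if state in ("ASC", "ASC-ER-stress"):
            mu[mod == "asc"] *= _ASC_STATE_BOOST
        if state == "ASC-ER-stress":
            mu[mod == "er"] *= 1.0 + _ER_UP
    elif branch == "non-ASC":
        mu[mod == "inflam"] *= 1.0 + _INFLAM_UP * r
    # totals are NOT renormalized after module effects: up-regulated programs
    # (notably the terminal secretory load) add to total mRNA content on top
    # of the division-wise growth factor, as they do in differentiating ASCs
    scale = config.mrna_scale_per_division ** division
    return mu * (config.base_total_umi / base.sum()) * scale


def _spike_pool(config: SimulationConfig) -> pd.Series:
    """Known spike-in molecule counts: a fixed geometric ladder."""
    ids = [f"ERCC-{i:05d}" for i in range(config.n_spikes)]
    mol = 4.0 * 2.0 ** (np.arange(config.n_spikes) % 8)
    return pd.Series(mol, index=pd.Index(ids, name="spike_id"), name="molecules")


def _spike_means(config: SimulationConfig, spikes: pd.Series) -> np.ndarray:
    """Expected spike counts per cell at capture 1: ~10% of a division-0 library."""
    if config.n_spikes == 0:
        return np.zeros(0)
    target = 0.1 * config.base_total_umi
    return spikes.to_numpy() * (target / spikes.sum())


def _assign_truth(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    divs = _division_grid(config)
    occ = _occupancy(config)
    division = rng.choice(divs, size=config.n_cells, p=occ)
    bp = config.branch_point_division
    d_max = int(divs.max()) if divs.size else 0

    branch = np.where(division < bp, "pre-branch", "")
    post = division >= bp
    is_asc = rng.random(config.n_cells) < config.asc_fraction
    branch = np.where(post & is_asc, "ASC-destined", branch)
    branch = np.where(post & ~is_asc, "non-ASC", branch)

    state = np.full(config.n_cells, "actB", dtype=object)
    state[division == 0] = "nB"
    terminal = (branch == "ASC-destined") & (division == d_max)
    er = rng.random(config.n_cells) < config.er_stress_fraction
    state[terminal & ~er] = "ASC"
    state[terminal & er] = "ASC-ER-stress"

    program = np.array(
        [f"d{d}|{b}|{s}" for d, b, s in zip(division, branch, state)], dtype=object
    )
    index = pd.Index([f"cell_{i:05d}" for i in range(config.n_cells)], name="cell")
    return pd.DataFrame(
        {
            "division": division.astype(int),
            "branch": branch,
            "state": state,
            "program": program,
        },
        index=index,
    )


def _all_programs(config: SimulationConfig) -> list[tuple[int, str, str]]:
    """Every (division, branch, state) combination the generator can emit."""
    bp = config.branch_point_division
    divs = _division_grid(config)
    d_max = int(divs.max()) if divs.size else 0
    out: list[tuple[int, str, str]] = []
    for d in divs:
        if d < bp:
            out.append((int(d), "pre-branch", "nB" if d == 0 else "actB"))
        else:
            if d == d_max:
                out.append((int(d), "ASC-destined", "ASC"))
                out.append((int(d), "ASC-destined", "ASC-ER-stress"))
            else:
                out.append((int(d), "ASC-destined", "nB" if d == 0 else "actB"))
            out.append((int(d), "non-ASC", "nB" if d == 0 else "actB"))
    return out


def simulate_experiment(
    config: SimulationConfig, noiseless: bool = False
) -> tuple[ad.AnnData, pd.Series]:
    """Generate a UMI count experiment with ground truth.

    Returns an :class:`anndata.AnnData` (cells x genes; spike rows flagged in
    ``var['is_spike']``; per-cell truth in ``obs``) and the spike-in molecule
    reference as a Series.  With ``noiseless=True`` the matrix holds expected
    counts (capture efficiency 1, no sampling noise) — the generating programs
    themselves, used for exact-recovery checks.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes, modules = _gene_names(config)
    base = _base_means(config, rng)
    spikes = _spike_pool(config)
    spike_mu = _spike_means(config, spikes)
    truth = _assign_truth(config, rng)

    mean_rows = np.empty((config.n_cells, config.n_genes + config.n_spikes))
    prog_cache: dict[str, np.ndarray] = {}
    for i, (d, b, s, p) in enumerate(
        zip(truth["division"], truth["branch"], truth["state"], truth["program"])
    ):
        if p not in prog_cache:
            prog_cache[p] = program_mean(base, modules, d, b, s, config)
        mean_rows[i, : config.n_genes] = prog_cache[p]
        mean_rows[i, config.n_genes :] = spike_mu

    if noiseless:
        counts = mean_rows
    else:
        sigma = np.sqrt(np.log1p(config.libsize_cv**2))
        capture = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=config.n_cells)
        m = mean_rows * capture[:, None]
        if config.nb_dispersion > 0:
            size = 1.0 / config.nb_dispersion
            with np.errstate(divide="ignore", invalid="ignore"):
                p = size / (size + m)
            p = np.where(m > 0, p, 1.0)
            counts = rng.negative_binomial(size, p).astype(np.float64)
        else:
            counts = rng.poisson(m).astype(np.float64)

    var = pd.DataFrame(
        {
            "module": pd.concat([modules, pd.Series("spike", index=spikes.index)]),
            "is_spike": np.r_[
                np.zeros(config.n_genes, bool), np.ones(config.n_spikes, bool)
            ],
        }
    )
    var.index.name = "gene"
    adata = ad.AnnData(X=counts, obs=truth, var=var)
    adata.uns["unit"] = "expected counts" if noiseless else "raw UMI"
    adata.uns["config"] = {
        "mrna_scale_per_division": config.mrna_scale_per_division,
        "branch_point_division": config.branch_point_division,
        "seed": config.seed,
    }
    # generating program means (genes x programs), the recoverable truth
    progs = _all_programs(config)
    pm = pd.DataFrame(
        {
            f"d{d}|{b}|{s}": program_mean(base, modules, d, b, s, config)
            for d, b, s in progs
        },
        index=genes,
    )
    adata.uns["program_means"] = pm
    adata.uns["spike_means"] = pd.Series(spike_mu, index=spikes.index)
    return adata, spikes


def _panel_program(
    label: str, pm: pd.DataFrame, config: SimulationConfig
) -> np.ndarray:
    """Mean biological profile of one sorted bulk population.

    Mid-ladder divisions contain both eventual branches (sorting is by
    division only), so their profile is the asc_fraction-weighted mixture;
    '8-' is the non-ASC terminal program and '8+' the ASC program with its
    ER-stress sub-state mixed in.
    """
    f = config.asc_fraction
    g = config.er_stress_fraction
    d_max = int(max(config.divisions))

    def col(d: int, b: str, s: str) -> np.ndarray:
        return pm[f"d{d}|{b}|{s}"].to_numpy()

    if label == "8-":
        return col(d_max, "non-ASC", "actB")
    if label == "8+":
        return (1 - g) * col(d_max, "ASC-destined", "ASC") + g * col(
            d_max, "ASC-destined", "ASC-ER-stress"
        )
    d = int(label)
    if d < config.branch_point_division:
        return col(d, "pre-branch", "nB" if d == 0 else "actB")
    return f * col(d, "ASC-destined", "actB") + (1 - f) * col(d, "non-ASC", "actB")


def simulate_bulk_reference(
    config: SimulationConfig, adata: ad.AnnData
) -> ReferencePanel:
    """Emit bulk replicate profiles per reference label with spike rows.

    Profiles are program means (1000-cell pools) perturbed by per-gene
    multiplicative lognormal replicate noise of sdlog ``bulk_noise_sd``;
    zero noise yields identical replicates within a label.
    """
    if config.bulk_replicates < 1:
        raise ValueError("bulk_replicates must be >= 1")
    rng = np.random.default_rng(config.seed + 777)
    pm: pd.DataFrame = adata.uns["program_means"]
    spike_mu: pd.Series = adata.uns["spike_means"]
    n_cells_bulk = 1000

    labels = [l for l in PANEL_LABELS if l in _valid_labels(config)]
    cols: dict[str, np.ndarray] = {}
    lab_map: dict[str, str] = {}
    for lab in labels:
        bio = _panel_program(lab, pm, config) * n_cells_bulk
        spk = spike_mu.to_numpy() * n_cells_bulk
        prof = np.concatenate([bio, spk])
        for r in range(config.bulk_replicates):
            if config.bulk_noise_sd > 0:
                noise = rng.lognormal(
                    -0.5 * config.bulk_noise_sd**2,
                    config.bulk_noise_sd,
                    size=prof.size,
                )
            else:
                noise = 1.0
            name = f"{lab}_rep{r + 1}"
            cols[name] = prof * noise
            lab_map[name] = lab
    index = pd.Index(
        list(pm.index) + list(spike_mu.index), name="gene"
    )
    mat = pd.DataFrame(cols, index=index)
    return ReferencePanel(matrix=mat, labels=pd.Series(lab_map, name="label"))


def _valid_labels(config: SimulationConfig) -> set[str]:
    divs = {int(d) for d in config.divisions}
    d_max = max(divs) if divs else 0
    out = {str(d) for d in divs if d != d_max and str(d) in PANEL_LABELS}
    if d_max in divs:
        out |= {"8-", "8+"}
    return out


def simulate_regulons(
    config: SimulationConfig,
    n_factors: int = 10,
    targets_per_factor: int = 20,
    aice_fraction: float = 0.65,
) -> dict[str, dict]:
    """Synthetic regulons coupled to the generator's modules.

    Each factor is a marker gene whose targets are drawn from the factor's
    own module, so regulon activity co-varies with factor expression across
    states by construction.  Motif annotations are tagged AP-1/AICE/other
    with an AICE share of ``aice_fraction`` among AP-1-family tags.
    """
    rng = np.random.default_rng(config.seed + 1234)
    genes, modules = _gene_names(config)
    factors: dict[str, dict] = {}
    mods = [m for m in config.module_sizes if config.module_sizes[m] > 1]
    for i in range(n_factors):
        mod = mods[i % len(mods)]
        members = [g for g in genes if modules[g] == mod]
        factor = members[(i // len(mods)) % len(members)]
        pool = [g for g in members if g != factor]
        k = min(targets_per_factor, len(pool))
        targets = list(rng.choice(pool, size=k, replace=False))
        n_motifs = int(rng.integers(8, 15))
        n_other = max(1, round(0.1 * n_motifs))
        n_ap1_family = n_motifs - n_other
        n_aice = round(aice_fraction * n_ap1_family)
        tags = (
            ["AICE"] * n_aice
            + ["AP-1"] * (n_ap1_family - n_aice)
            + ["other"] * n_other
        )
        factors[factor] = {"targets": targets, "motifs": tags}
    return factors
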