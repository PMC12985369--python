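"""Synthetic spot-level and cell-level datasets with planted ground truth.

The generator emulates the statistical structure of a fibrotic-lung spatial
study: spots are cell mixtures drawn from niche-specific Dirichlet
compositions laid out in contiguous lattice blocks, single-cell/nucleus
atlases are negative-binomial draws around cell-type base profiles, and
signals for every downstream stage are planted explicitly — colocalized
cell-type pairs (shared high-concentration niches), condition-specific
ligand-receptor co-expression, transcription-factor regulons, and
compositional abundance shifts between conditions.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
sub-streams, so identical configurations reproduce identical data
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class LRPlant:
    """A planted ligand-receptor signal: `ligand` is induced in `sender`
    cells of `condition`; `receptor` is constitutively elevated in
    `receiver`. `niche` is the niche whose spots the pair shares (None if
    the pair deliberately spans niches)."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    condition: str = "ILD"
    niche: str | None = None


@dataclass(frozen=True)
class RegulonPlant:
    """A planted regulon: `targets` have their mean expression multiplied by
    `effect` in `cell_type`; the TF gene itself is elevated the same way."""

    tf: str
    targets: tuple[str, ...]
    effect: float
    cell_type: str


@dataclass
class GeneratorConfig:
    n_genes: int = 160
    n_cell_types: int = 12
    n_spots_per_sample: int = 500
    n_samples_per_condition: int = 2
    conditions: tuple[str, str] = ("control", "ILD")
    cell_types: tuple[str, ...] = ()
    compartments: dict = field(default_factory=dict)
    # niche id -> Dirichlet concentration vector over cell types
    niche_definitions: dict = field(default_factory=dict)
    # condition -> tuple of niche ids, one per contiguous lattice block
    niche_spatial_layout: dict = field(default_factory=dict)
    mean_cells_per_spot: float = 20.0
    nb_dispersion: float = 2.0
    cells_per_sample: int = 1200
    planted_lr_pairs: tuple = ()
    lr_effect: float = 4.0
    planted_regulons: tuple = ()
    # cell type -> natural-log fold change of abundance in the second condition
    planted_abundance_shifts: dict = field(default_factory=dict)
    reference_cell_type: str = "Arterial"
    n_mito_genes: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.n_genes <= 0:
            raise ConfigurationError("empty gene set")
        if len(self.cell_types) != self.n_cell_types:
            raise ConfigurationError("cell_types length must equal n_cell_types")
        for nid, alpha in self.niche_definitions.items():
            a = np.asarray(alpha, dtype=float)
            if a.shape != (self.n_cell_types,) or np.any(a <= 0):
                raise ConfigurationError(
                    f"niche {nid!r}: concentration must be strictly positive "
                    f"with length {self.n_cell_types}"
                )
        for cond, layout in self.niche_spatial_layout.items():
            for nid in layout:
                if nid not in self.niche_definitions:
                    raise ConfigurationError(
                        f"layout for {cond!r} references unknown niche {nid!r}"
                    )
        for p in self.planted_lr_pairs:
            for t in (p.sender, p.receiver):
                if t not in self.cell_types:
                    raise ConfigurationError(f"planted L-R type {t!r} unknown")
        for r in self.planted_regulons:
            if r.cell_type not in self.cell_types:
                raise ConfigurationError(f"regulon cell type {r.cell_type!r} unknown")
        shift = self.planted_abundance_shifts.get(self.reference_cell_type, 0.0)
        if shift != 0.0:
            raise ConfigurationError(
                f"reference cell type {self.reference_cell_type!r} must have "
                f"planted shift 0, got {shift}"
            )


@dataclass
class GroundTruth:
    """Planted truth, resolvable against the generated data."""

    spot_fractions: pd.DataFrame | None = None
    spot_type_counts: pd.DataFrame | None = None
    cells_per_spot: pd.Series | None = None
    colocalized_pairs: dict = field(default_factory=dict)
    lr_triples: list = field(default_factory=list)
    driver_tfs: list = field(default_factory=list)
    driver_ligands: list = field(default_factory=list)
    shifted_types: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "colocalized_pairs": {
                c: sorted(map(list, prs)) for c, prs in self.colocalized_pairs.items()
            },
            "lr_triples": [dataclasses.asdict(t) for t in self.lr_triples],
            "driver_tfs": list(self.driver_tfs),
            "driver_ligands": list(self.driver_ligands),
            "shifted_types": self.shifted_types,
        }
        if self.spot_fractions is not None:
            doc["spot_fractions"] = {
                "index": list(self.spot_fractions.index),
                "columns": list(self.spot_fractions.columns),
                "values": self.spot_fractions.to_numpy().tolist(),
            }
            doc["spot_type_counts"] = self.spot_type_counts.to_numpy().astype(int).tolist()
            doc["cells_per_spot"] = self.cells_per_spot.to_numpy().astype(int).tolist()
        return json.dumps(doc, sort_keys=True)


# ---------------------------------------------------------------------------
# default study conditions

_DEFAULT_TYPES = (
    "AT1", "AT2", "trAT", "AberrantTrAT",
    "alvF", "MyoF", "advF", "SMC",
    "Arterial", "gCap", "alvMac", "Tcell",
)

_DEFAULT_COMPARTMENTS = {
    "AT1": "epithelial", "AT2": "epithelial", "trAT": "epithelial",
    "AberrantTrAT": "epithelial",
    "alvF": "stromal", "MyoF": "stromal", "advF": "stromal", "SMC": "stromal",
    "Arterial": "endothelial", "gCap": "endothelial",
    "alvMac": "immune", "Tcell": "immune",
}

_HIGH_ALPHA, _LOW_ALPHA = 5.0, 0.08

_CONTROL_NICHES = {
    "n_alv1": ("AT1", "gCap"),
    "n_alv2": ("AT2", "alvF"),
    "n_trans": ("trAT", "AberrantTrAT"),
    "n_vessel": ("Arterial", "SMC"),
    "n_adv": ("advF", "Tcell"),
    "n_fib": ("MyoF", "alvMac"),
}

_ILD_NICHES = {
    "m_mixed1": ("AT1", "gCap", "AT2", "alvF", "trAT", "AberrantTrAT"),
    "m_mixed2": ("Arterial", "SMC", "advF", "Tcell", "MyoF", "alvMac"),
}


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The study conditions every test and the acceptance run are built on.

    Control tissue has six two-type niches (intact anatomical
    compartmentalization); the disease condition collapses them into two
    six-type mixed niches (loss of modularity). Three L-R pairs, three
    regulons driven by two upstream ligands, and abundance shifts for two
    cell types are planted.
    """
    types = _DEFAULT_TYPES
    idx = {t: i for i, t in enumerate(types)}

    def alpha_for(high):
        a = np.full(len(types), _LOW_ALPHA)
        for t in high:
            a[idx[t]] = _HIGH_ALPHA if len(high) == 2 else 2.5
        return tuple(a)

    niches = {nid: alpha_for(h) for nid, h in _CONTROL_NICHES.items()}
    niches.update({nid: alpha_for(h) for nid, h in _ILD_NICHES.items()})

    layout = {
        "control": tuple(_CONTROL_NICHES),
        "ILD": ("m_mixed1", "m_mixed2") * 3,
    }

    regulon_targets = {
        "SOX4": tuple(f"SOX4_T{i}" for i in range(8)),
        "TP63": tuple(f"TP63_T{i}" for i in range(8)),
        "RUNX2": tuple(f"RUNX2_T{i}" for i in range(8)),
    }
    cfg = GeneratorConfig(
        cell_types=types,
        compartments=dict(_DEFAULT_COMPARTMENTS),
        niche_definitions=niches,
        niche_spatial_layout=layout,
        planted_lr_pairs=(
            LRPlant("PLAU", "PLAUR", "alvF", "AberrantTrAT", "ILD", "m_mixed1"),
            LRPlant("IGF1", "IGF1R", "trAT", "AberrantTrAT", "ILD", "m_mixed1"),
            LRPlant("SPP1", "ITGAV", "alvMac", "MyoF", "ILD", "m_mixed2"),
        ),
        planted_regulons=tuple(
            RegulonPlant(tf, tg, 3.0, "AberrantTrAT")
            for tf, tg in regulon_targets.items()
        ),
        planted_abundance_shifts={"MyoF": 1.0, "AT1": -0.7, "Arterial": 0.0},
        reference_cell_type="Arterial",
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# gene universe and base profiles

def _gene_names(config: GeneratorConfig) -> list[str]:
    names: list[str] = [f"MT-G{i}" for i in range(config.n_mito_genes)]
    planted: list[str] = []
    for r in config.planted_regulons:
        planted.append(r.tf)
        planted.extend(r.targets)
    for p in config.planted_lr_pairs:
        planted.extend([p.ligand, p.receptor])
    seen = set(names)
    for g in planted:
        if g not in seen:
            names.append(g)
            seen.add(g)
    i = 0
    while len(names) < config.n_genes:
        g = f"G{i:04d}"
        if g not in seen:
            names.append(g)
            seen.add(g)
        i += 1
    if len(names) > config.n_genes:
        raise ConfigurationError(
            f"n_genes={config.n_genes} too small for planted genes ({len(names)})"
        )
    return names


def base_profiles(config: GeneratorConfig) -> pd.DataFrame:
    """Cell-type × gene mean-expression matrix (raw-count scale).

    Each type receives a block of marker genes with boosted means so that
    profiles are linearly distinguishable; planted TFs and regulon targets
    are multiplied by the regulon effect size in the regulon's cell type,
    and planted receptors are constitutively elevated in their receiver
    type.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    genes = _gene_names(config)
    G, T = len(genes), config.n_cell_types
    baseline = rng.gamma(shape=2.0, scale=0.25, size=G)  # mean ~0.5 per gene
    mu = np.tile(baseline, (T, 1))
    gi = {g: j for j, g in enumerate(genes)}
    ti = {t: i for i, t in enumerate(config.cell_types)}

    # mito genes: shared moderate expression so QC has something to measure
    mu[:, : config.n_mito_genes] = 1.0

    # planted genes get a fixed, type-uniform baseline so planted effects are
    # exactly multiplicative on a known base
    for r in config.planted_regulons:
        mu[:, gi[r.tf]] = 1.0
        for tg in r.targets:
            mu[:, gi[tg]] = 1.0
    # receptors are near-silent outside their receiver type, so the >5%
    # receptor-expression filter is a real gate
    for p in config.planted_lr_pairs:
        mu[:, gi[p.ligand]] = 0.5
        mu[:, gi[p.receptor]] = 0.02

    # marker blocks: at most 8 filler genes per type boosted; remaining
    # filler genes stay flat across types (a null background)
    filler = [j for j, g in enumerate(genes) if g.startswith("G")]
    per_type = min(max(len(filler) // T, 1), 8)
    for i in range(T):
        block = filler[i * per_type : (i + 1) * per_type]
        mu[i, block] *= 6.0

    # planted regulons: TF and targets elevated in the regulon's cell type
    for r in config.planted_regulons:
        i = ti[r.cell_type]
        mu[i, gi[r.tf]] *= r.effect
        for tg in r.targets:
            mu[i, gi[tg]] *= r.effect

    # planted receptors: constitutive expression in the receiver type only
    for p in config.planted_lr_pairs:
        mu[ti[p.receiver], gi[p.receptor]] = max(2.0, config.lr_effect / 2)

    return pd.DataFrame(mu, index=list(config.cell_types), columns=genes)


def _nb_draw(rng, mean, theta):
    """Negative-binomial draw with mean `mean` and dispersion `theta`
    (var = mean + mean^2/theta); `theta` may be an array."""
    mean = np.asarray(mean, dtype=float)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), mean.shape)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


# ---------------------------------------------------------------------------
# cell atlas

def _sample_type_counts(config: GeneratorConfig, rng) -> dict:
    """Per (condition, sample) cell counts per type, honoring planted shifts."""
    T = config.n_cell_types
    p0 = np.full(T, 1.0 / T)
    out = {}
    for cond in config.conditions:
        p = p0.copy()
        if cond == config.conditions[1]:
            for t, lfc in config.planted_abundance_shifts.items():
                p[config.cell_types.index(t)] *= np.exp(lfc)
        p = p / p.sum()
        for s in range(config.n_samples_per_condition):
            out[(cond, s)] = rng.multinomial(config.cells_per_sample, p)
    return out


def generate_cell_atlas(config: GeneratorConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a labeled cell×gene atlas with planted regulons and shifts.

    Counts are negative-binomial around the cell-type base profiles with one
    global dispersion. Metadata: cell_type, compartment, sample, condition.
    """
    config.validate()
    profiles = base_profiles(config)
    ss = np.random.SeedSequence([config.seed, 202])
    rng_comp = np.random.default_rng(ss.spawn(1)[0])
    counts_by_sample = _sample_type_counts(config, rng_comp)

    blocks, obs_rows = [], []
    sample_streams = ss.spawn(len(counts_by_sample))
    for ((cond, s), type_counts), sub in zip(
        sorted(counts_by_sample.items()), sample_streams
    ):
        rng = np.random.default_rng(sub)
        sample_id = f"{cond}_s{s}"
        for i, t in enumerate(config.cell_types):
            n = int(type_counts[i])
            if n == 0:
                continue
            mu = np.tile(profiles.loc[t].to_numpy(), (n, 1))
            blocks.append(_nb_draw(rng, mu, config.nb_dispersion))
            obs_rows.extend(
                {
                    "cell_type": t,
                    "compartment": config.compartments.get(t, "unknown"),
                    "sample": sample_id,
                    "condition": cond,
                }
                for _ in range(n)
            )
    X = sparse.csr_matrix(np.vstack(blocks))
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell_{i:06d}" for i in range(len(obs))]
    atlas = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=profiles.columns))

    truth = GroundTruth(
        driver_tfs=[r.tf for r in config.planted_regulons],
        driver_ligands=_driver_ligands(config),
        shifted_types={
            t: lfc for t, lfc in config.planted_abundance_shifts.items() if lfc != 0
        },
    )
    return atlas, truth


def _driver_ligands(config: GeneratorConfig) -> list[str]:
    """Planted driver ligands: pairs whose receiver hosts the planted regulons."""
    targets = {r.cell_type for r in config.planted_regulons}
    return sorted({p.ligand for p in config.planted_lr_pairs if p.receiver in targets})


def plant_lr_coexpression(spot_dataset, atlas: ad.AnnData, planted_lr_pairs,
                          config: GeneratorConfig) -> ad.AnnData:
    """Upregulate each planted ligand in its sender type, only in cells of
    the planted condition. Receptors are already constitutive in the base
    profiles; this touches ligand counts only, so all other entries are
    byte-identical to the input."""
    if not planted_lr_pairs:
        return atlas
    atlas = atlas.copy()
    X = atlas.X.tolil() if sparse.issparse(atlas.X) else atlas.X
    gi = {g: j for j, g in enumerate(atlas.var_names)}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    for p in planted_lr_pairs:
        for g, t in ((p.ligand, p.sender),):
            if g not in gi:
                raise ConfigurationError(f"planted gene {g!r} absent from atlas")
            if t not in set(atlas.obs["cell_type"]):
                raise ConfigurationError(f"planted type {t!r} absent from atlas")
            mask = (
                (atlas.obs["cell_type"] == t)
                & (atlas.obs["condition"] == p.condition)
            ).to_numpy()
            n = int(mask.sum())
            if n == 0:
                continue
            boosted_mean = max(2.0, config.lr_effect)
            X[np.where(mask)[0], gi[g]] = _nb_draw(
                rng, np.full(n, boosted_mean), config.nb_dispersion
            )
    atlas.X = sparse.csr_matrix(X)
    return atlas


# ---------------------------------------------------------------------------
# spot dataset

def _hex_positions(n_spots: int) -> pd.DataFrame:
    """Row/column indices on a hexagonal lattice in the Space Ranger
    convention (array_col parity matches array_row parity)."""
    ncol = int(np.ceil(np.sqrt(n_spots)))
    rows = np.repeat(np.arange((n_spots + ncol - 1) // ncol), ncol)[:n_spots]
    cols = np.tile(np.arange(ncol), (n_spots + ncol - 1) // ncol)[:n_spots]
    return pd.DataFrame({"array_row": rows, "array_col": 2 * cols + rows % 2})


def true_colocalized_pairs(config: GeneratorConfig, high_alpha: float = 1.0) -> dict:
    """Per condition, unordered cell-type pairs sharing a high-concentration
    niche (alpha > `high_alpha`) in that condition's layout."""
    out = {}
    for cond, layout in config.niche_spatial_layout.items():
        pairs = set()
        for nid in set(layout):
            a = np.asarray(config.niche_definitions[nid])
            high = [config.cell_types[i] for i in np.where(a > high_alpha)[0]]
            pairs.update(
                tuple(sorted((x, y)))
                for k, x in enumerate(high)
                for y in high[k + 1 :]
            )
        out[cond] = pairs
    return out


def generate_spot_dataset(
    config: GeneratorConfig, atlas_profiles: pd.DataFrame
) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate spot×gene counts on a hexagonal lattice.

    Each spot's composition is a Dirichlet draw from its niche (niches are
    contiguous bands of lattice rows); cells per spot are Poisson; the spot
    count vector is the sum of that many per-cell negative-binomial profile
    draws (drawn directly as NB with aggregated mean and dispersion).
    """
    config.validate()
    if not config.niche_spatial_layout:
        raise ConfigurationError("niche layout covers no spots")
    genes = list(atlas_profiles.columns)
    T = config.n_cell_types
    mu = atlas_profiles.loc[list(config.cell_types)].to_numpy()
    ss = np.random.SeedSequence([config.seed, 404])
    n_samples = len(config.conditions) * config.n_samples_per_condition
    streams = iter(ss.spawn(n_samples))

    Xs, obs_rows, frac_rows, count_rows, k_rows, barcodes = [], [], [], [], [], []
    for cond in config.conditions:
        layout = config.niche_spatial_layout[cond]
        for s in range(config.n_samples_per_condition):
            rng = np.random.default_rng(next(streams))
            S = config.n_spots_per_sample
            pos = _hex_positions(S)
            nrow = pos["array_row"].max() + 1
            band = np.minimum(
                (pos["array_row"] * len(layout)) // max(nrow, 1), len(layout) - 1
            )
            niche_ids = np.asarray([layout[b] for b in band])

            frac = np.empty((S, T))
            for nid in set(layout):
                m = niche_ids == nid
                frac[m] = rng.dirichlet(
                    np.asarray(config.niche_definitions[nid]), size=int(m.sum())
                )
            k = np.maximum(rng.poisson(config.mean_cells_per_spot, size=S), 1)
            ncell = rng.multinomial(k, frac)

            X = np.zeros((S, len(genes)), dtype=np.int64)
            for i in range(T):
                nt = ncell[:, i]
                m = nt > 0
                if not m.any():
                    continue
                agg_theta = nt[m, None] * config.nb_dispersion
                agg_mu = nt[m, None] * mu[i][None, :]
                X[m] += _nb_draw(rng, agg_mu, agg_theta)

            sample_id = f"{cond}_s{s}"
            bcs = [f"{sample_id}_spot{j:05d}" for j in range(S)]
            barcodes.extend(bcs)
            Xs.append(X)
            obs_rows.append(
                pd.DataFrame(
                    {
                        "sample": sample_id,
                        "condition": cond,
                        "niche": niche_ids,
                        "array_row": pos["array_row"].to_numpy(),
                        "array_col": pos["array_col"].to_numpy(),
                    },
                    index=bcs,
                )
            )
            frac_rows.append(frac)
            count_rows.append(ncell)
            k_rows.append(k)

    obs = pd.concat(obs_rows)
    spots = ad.AnnData(
        X=sparse.csr_matrix(np.vstack(Xs)),
        obs=obs,
        var=pd.DataFrame(index=genes),
    )
    spots.obsm["spatial"] = obs[["array_row", "array_col"]].to_numpy()
    types = list(config.cell_types)
    truth = GroundTruth(
        spot_fractions=pd.DataFrame(np.vstack(frac_rows), index=barcodes, columns=types),
        spot_type_counts=pd.DataFrame(np.vstack(count_rows), index=barcodes, columns=types),
        cells_per_spot=pd.Series(np.concatenate(k_rows), index=barcodes),
        colocalized_pairs=true_colocalized_pairs(config),
    )
    return spots, truth


# ---------------------------------------------------------------------------
# composition counts and driver-prioritization inputs

def simulate_composition_counts(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample×cell-type count table plus covariates, drawn from the same
    per-sample multinomial composition machinery as the atlas (without
    materializing gene counts) — used for abundance-shift analyses."""
    cfg = dataclasses.replace(config) if seed is None else dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]).spawn(1)[0])
    counts = _sample_type_counts(cfg, rng)
    rows, meta = [], []
    for (cond, s), v in sorted(counts.items()):
        rows.append(v)
        meta.append({"sample": f"{cond}_s{s}", "condition": cond})
    table = pd.DataFrame(
        np.vstack(rows),
        index=[m["sample"] for m in meta],
        columns=list(cfg.cell_types),
    )
    cov = pd.DataFrame(meta).set_index("sample")
    return table, cov


def make_potential_matrix(
    config: GeneratorConfig, n_decoy_ligands: int = 40, n_decoy_tfs: int = 7
) -> pd.DataFrame:
    """Ligand×TF regulatory-potential prior. Planted driver-ligand → planted-TF
    entries are high (0.7–1.0); everything else is low background (0–0.3)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
    tfs = [r.tf for r in config.planted_regulons] + [
        f"DECOY_TF{i}" for i in range(n_decoy_tfs)
    ]
    ligands = sorted({p.ligand for p in config.planted_lr_pairs}) + [
        f"DECOY_L{i}" for i in range(n_decoy_ligands)
    ]
    pot = rng.uniform(0.0, 0.3, size=(len(ligands), len(tfs)))
    drivers = set(_driver_ligands(config))
    planted_tfs = {r.tf for r in config.planted_regulons}
    for i, lg in enumerate(ligands):
        for j, tf in enumerate(tfs):
            if lg in drivers and tf in planted_tfs:
                pot[i, j] = rng.uniform(0.7, 1.0)
    return pd.DataFrame(pot, index=ligands, columns=tfs)


def receptor_map(config: GeneratorConfig) -> pd.DataFrame:
    """Ligand → receptor-gene map covering planted pairs and decoys (decoy
    receptors point at a gene absent from the atlas, so they can never pass
    the expression filter)."""
    rows = [
        {"ligand": p.ligand, "receptor_genes": p.receptor}
        for p in config.planted_lr_pairs
    ]
    for i in range(60):
        rows.append({"ligand": f"DECOY_L{i}", "receptor_genes": f"DECOY_R{i}"})
    return pd.DataFrame(rows).drop_duplicates("ligand").set_index("ligand")


def generate_dataset(config: GeneratorConfig):
    """Full bundle: (atlas, spots, truth). Ligand co-expression is planted
    into the atlas; truth merges the atlas- and spot-level components."""
    atlas, truth_a = generate_cell_atlas(config)
    atlas = plant_lr_coexpression(None, atlas, config.planted_lr_pairs, config)
    spots, truth_s = generate_spot_dataset(config, base_profiles(config))
    truth = GroundTruth(
        spot_fractions=truth_s.spot_fractions,
        spot_type_counts=truth_s.spot_type_counts,
        cells_per_spot=truth_s.cells_per_spot,
        colocalized_pairs=truth_s.colocalized_pairs,
        lr_triples=list(config.planted_lr_pairs),
        driver_tfs=truth_a.driver_tfs,
        driver_ligands=truth_a.driver_ligands,
        shifted_types=truth_a.shifted_types,
    )
    return atlas, spots, truth
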