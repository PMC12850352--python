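"""Synthetic degradome generator with ground truth.

The generator emulates the structure of plasma peptidomics data: a few
proteolytic hotspot bonds per precursor protein cut it into parent
fragments; exopeptidase nibbling then trims single residues off either
end, producing nested "ladders" of peptides that share the hotspot-side
terminus with geometrically decaying abundance.  Per-sample intensities
are log-normal around a peptide baseline; group-specific protease
dysregulation multiplies every peptide generated by an affected cleavage
site (precursor abundance itself stays flat); detection dropout is
intensity-dependent (logistic in log intensity) plus a small
missing-completely-at-random floor.  Pooled reference replicates and
noise-free PRM-style panels round out the inputs the pipeline consumes.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import ProteinDatabase, ProteinRecord
from .io import GroupDesign

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic degradome.

    Defaults model a two-group case/control cohort of 15 samples per
    group with 20 precursor proteins carrying 3 dysregulated hotspots
    each at a two-fold activity effect under moderate log-normal noise
    (sigma = 0.5 on the natural-log scale).
    """

    seed: int = 0
    n_proteins: int = 20
    protein_length: int = 360
    hotspots_per_protein: int = 3
    min_hotspot_margin: int = 40       # residues kept clear of chain ends
    min_hotspot_separation: int = 40
    effect_fold: float = 2.0           # per-site activity multiplier magnitude
    group_names: tuple[str, ...] = ("Ctr", "Case")
    group_sizes: tuple[int, ...] = (15, 15)
    group_exponents: tuple[float, ...] = (0.0, 1.0)  # multiplier = fold**(dir*exp)
    max_trim: int = 4                  # exopeptidase ladder depth
    trim_decay: float = 0.5            # abundance factor per trimmed residue
    min_peptide_length: int = 7
    log_mu: float = 14.0               # baseline ln-intensity mean
    log_sigma_base: float = 1.0        # between-peptide spread
    noise_sigma: float = 0.5           # within-group biological noise (ln)
    sample_factor_sigma: float = 0.1   # per-sample loading factor (ln)
    dropout_mcar: float = 0.02
    dropout_steepness: float = 1.5
    dropout_midpoint_quantile: float = 0.05  # of ln-intensity distribution
    dropout_midpoint: float | None = None    # absolute ln-intensity override
    reference_replicates: int = 5
    reference_noise_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not (len(self.group_names) == len(self.group_sizes) == len(self.group_exponents)):
            raise ValueError("group names, sizes and exponents must align")
        if any(n < 3 for n in self.group_sizes):
            raise ValueError("group sizes must be >=3 so presence filters can pass")
        if self.effect_fold <= 0 or self.trim_decay <= 0:
            raise ValueError("multipliers must be positive")

    def design(self) -> GroupDesign:
        mapping = {
            f"{g}_{i + 1:02d}": g
            for g, n in zip(self.group_names, self.group_sizes)
            for i in range(n)
        }
        return GroupDesign(mapping, list(self.group_names))


@dataclass
class Hotspot:
    protein: str
    bond: int
    direction: int            # +1 enhanced, -1 reduced proteolysis
    multiplier: float         # per-site magnitude (effect_fold)


@dataclass
class GroundTruth:
    """Planted hotspots and per-peptide provenance."""

    hotspots: list[Hotspot]
    peptides: pd.DataFrame    # peptide, protein, start, end, sites, trim, base

    def hotspot_map(self) -> dict[tuple[str, int], int]:
        """(protein, bond) -> planted direction."""
        return {(h.protein, h.bond): h.direction for h in self.hotspots}

    def to_json(self, path) -> None:
        payload = {
            "hotspots": [asdict(h) for h in self.hotspots],
            "peptides": self.peptides.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def simulate_proteome(config: SimulationConfig, db: ProteinDatabase | None = None) -> ProteinDatabase:
    """Random protein sequences (i.i.d. residues), or pass a database through."""
    if db is not None:
        return db
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_proteins):
        seq = "".join(rng.choice(_RESIDUES, size=config.protein_length))
        records.append(ProteinRecord(f"SIM{i + 1:03d}", seq))
    return ProteinDatabase(records)


def _place_hotspots(rng: np.random.Generator, L: int, cfg: SimulationConfig) -> list[int]:
    lo, hi = cfg.min_hotspot_margin, L - cfg.min_hotspot_margin
    for _ in range(1000):
        bonds = np.sort(rng.integers(lo, hi + 1, size=cfg.hotspots_per_protein))
        if cfg.hotspots_per_protein == 1 or np.diff(bonds).min() >= cfg.min_hotspot_separation:
            return [int(b) for b in bonds]
    raise ValueError("could not place hotspots; protein too short for the config")


def simulate_degradome(
    proteins: ProteinDatabase, config: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth, GroupDesign]:
    """Generate the peptide x sample intensity matrix plus ground truth.

    Returns true (pre-dropout) intensities; apply
    :func:`inject_missingness` for the observed matrix.
    """
    rng = np.random.default_rng(config.seed + 1)
    design = config.design()
    hotspots: list[Hotspot] = []
    pep_rows: list[dict] = []

    for rec in proteins:
        L = rec.length
        bonds = _place_hotspots(rng, L, config)
        directions = rng.choice([-1, 1], size=len(bonds))
        site_mult = {}
        for b, d in zip(bonds, directions):
            hotspots.append(Hotspot(rec.accession, int(b), int(d), config.effect_fold))
            site_mult[int(b)] = (int(d), config.effect_fold)
        boundaries = [0] + bonds + [L]
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            s0, e0 = a + 1, b
            sites = [j for j in (a, b) if 0 < j < L]
            base_parent = float(np.exp(rng.normal(config.log_mu, config.log_sigma_base)))
            species = [(s0, e0, 0)]
            species += [(s0 + t, e0, t) for t in range(1, config.max_trim + 1)]
            species += [(s0, e0 - t, t) for t in range(1, config.max_trim + 1)]
            for s, e, trim in species:
                if e - s + 1 < config.min_peptide_length:
                    continue
                pep_rows.append(
                    {
                        "peptide": rec.sequence[s - 1 : e],
                        "protein": rec.accession,
                        "start": s,
                        "end": e,
                        "sites": sites,
                        "trim": trim,
                        "base": base_parent * config.trim_decay ** trim,
                    }
                )

    peptides = pd.DataFrame(pep_rows)
    dup = peptides["peptide"].duplicated(keep=False)
    if dup.any():  # astronomically unlikely for random sequences; drop cleanly
        peptides = peptides[~dup].reset_index(drop=True)

    site_lookup = {(h.protein, h.bond): h for h in hotspots}
    effects = np.ones((len(peptides), len(config.group_names)))
    for i, row in enumerate(peptides.itertuples()):
        for site in row.sites:
            h = site_lookup[(row.protein, site)]
            for g, expo in enumerate(config.group_exponents):
                effects[i, g] *= h.multiplier ** (h.direction * expo)

    samples = design.samples
    group_index = {g: k for k, g in enumerate(config.group_names)}
    sample_factors = np.exp(rng.normal(0.0, config.sample_factor_sigma, size=len(samples)))
    base = peptides["base"].to_numpy()[:, None]
    noise = np.exp(rng.normal(0.0, config.noise_sigma, size=(len(peptides), len(samples))))
    eff = np.stack(
        [effects[:, group_index[design.sample_to_group[s]]] for s in samples], axis=1
    )
    matrix = pd.DataFrame(
        base * eff * sample_factors[None, :] * noise,
        index=pd.Index(peptides["peptide"], name="peptide"),
        columns=samples,
    )
    truth = GroundTruth(hotspots=hotspots, peptides=peptides)
    return matrix, truth, design


def inject_missingness(
    matrix: pd.DataFrame, config: SimulationConfig, seed_offset: int = 2
) -> pd.DataFrame:
    """Intensity-dependent dropout plus an MCAR floor.

    Cell drop probability = mcar + (1 - mcar) * logistic(-k (ln I - m)),
    with the midpoint m at the configured quantile of the ln-intensity
    distribution.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    values = matrix.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_i = np.log(values)
    finite = log_i[np.isfinite(log_i)]
    if config.dropout_midpoint is not None:
        midpoint = config.dropout_midpoint
    else:
        midpoint = np.quantile(finite, config.dropout_midpoint_quantile) if finite.size else 0.0
    p_drop = config.dropout_mcar + (1.0 - config.dropout_mcar) * expit(
        -config.dropout_steepness * (log_i - midpoint)
    )
    drop = rng.random(values.shape) < p_drop
    out = matrix.copy()
    out.values[drop] = np.nan
    return out


def dropout_probability(log_intensity: np.ndarray, config: SimulationConfig, midpoint: float) -> np.ndarray:
    """Expected drop probability for given ln-intensities (for calibration checks)."""
    return config.dropout_mcar + (1.0 - config.dropout_mcar) * expit(
        -config.dropout_steepness * (log_intensity - midpoint)
    )


def make_reference(
    matrix: pd.DataFrame,
    config: SimulationConfig,
    apply_dropout: bool = True,
) -> pd.DataFrame:
    """Pooled-reference replicate runs for the sample matrix.

    The pooled true intensity of a peptide is the mean of its per-sample
    true intensities (equal-volume pooling); each replicate run multiplies
    it by log-normal technical noise and, optionally, passes through the
    dropout model.
    """
    rng = np.random.default_rng(config.seed + 3)
    pooled = matrix.mean(axis=1, skipna=True)
    reps = {}
    for r in range(config.reference_replicates):
        noise = np.exp(rng.normal(0.0, config.reference_noise_sigma, size=len(pooled)))
        reps[f"REF_{r + 1:02d}"] = pooled * noise
    runs = pd.DataFrame(reps, index=matrix.index)
    if apply_dropout:
        runs = inject_missingness(runs, config, seed_offset=4)
    return runs


# ---------------------------------------------------------------------------
# PRM-style panels

@dataclass
class PRMSimulation:
    amounts: pd.DataFrame      # member x sample true endogenous amounts
    light: pd.DataFrame        # endogenous intensities
    heavy: pd.DataFrame        # heavy-standard intensities
    reference: pd.Series       # pooled reference intensities per member
    calibration: pd.DataFrame  # columns: peptide, amount, ratio
    design: GroupDesign
    site_level: pd.Series      # per-sample true site abundance


def simulate_prm(
    members: Sequence[str] = ("PEPTIDEA", "PEPTIDEB", "PEPTIDEC"),
    config: SimulationConfig | None = None,
    noise_sigma: float = 0.0,
    n_calibration: int = 8,
) -> PRMSimulation:
    """Targeted panel for one peptide cluster with known site effect.

    Every member's endogenous amount is its weight times the sample's
    site-level abundance (cases carry the configured fold effect), so the
    planted case/control ratio is exact when ``noise_sigma`` is 0.  Heavy
    standards are spiked at fixed amounts; instrument response factors
    differ per member and cancel in light/heavy and sample/reference
    ratios.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed + 5)
    design = cfg.design()
    samples = design.samples
    group_index = {g: k for k, g in enumerate(cfg.group_names)}
    site = np.array(
        [
            cfg.effect_fold ** cfg.group_exponents[group_index[design.sample_to_group[s]]]
            for s in samples
        ]
    )
    site = site * np.exp(rng.normal(0.0, noise_sigma, size=len(samples)))
    weights = rng.uniform(0.5, 2.0, size=len(members))
    response = rng.uniform(0.2, 5.0, size=len(members))
    heavy_amount = rng.uniform(1.0, 3.0, size=len(members))

    amounts = pd.DataFrame(
        np.outer(weights, site), index=list(members), columns=samples
    )
    light = amounts.mul(response, axis=0)
    heavy = pd.DataFrame(
        np.tile((response * heavy_amount)[:, None], (1, len(samples))),
        index=list(members),
        columns=samples,
    )
    reference = pd.Series(
        response * weights * site.mean(), index=list(members), name="reference"
    )
    cal_rows = []
    dil = np.geomspace(0.125, 16, n_calibration)
    for m, h in zip(members, heavy_amount):
        for amount in dil:
            cal_rows.append({"peptide": m, "amount": amount, "ratio": amount / h})
    return PRMSimulation(
        amounts=amounts,
        light=light,
        heavy=heavy,
        reference=reference,
        calibration=pd.DataFrame(cal_rows),
        design=design,
        site_level=pd.Series(site, index=samples, name="site_level"),
    )
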