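"""Synthetic drug-combination screens for end-to-end testing.

The generator emulates the structure of a combination screen without any
external download:

* **Monotherapy** follows a Hill curve ``g(r) = 1 / (1 + (r/EC50)^h)`` on a
  log-spaced dose grid (growth fraction 1 = untreated, 0 = full inhibition).
* **Combination surfaces** follow the Bliss-independence null — the product
  of the two single-drug growth fractions — plus a localized Gaussian bump
  in log-dose space that injects synergy (positive amplitude) or antagonism
  (negative), plus i.i.d. Gaussian measurement noise. Full 5 x 5
  dose-response matrices are emitted per (pair, cell line), matching the
  common screening design.
* **Cell-line expression** is a latent-factor model: each cell draws a
  low-dimensional latent vector that both generates its expression profile
  (through a random loading matrix, plus noise) and shifts each drug's
  log-EC50 in that cell — so expression is genuinely informative about
  sensitivity, the property the cell-line encoder is meant to exploit.
* **SMILES** come from an embedded list of small valid molecules, extended
  by simple carbon chain growth when more drugs are requested than the list
  holds.

Every emitted quantity is recorded in :class:`GroundTruth`, enabling
recovery tests against the noise-free surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .io_types import (
    CellLineProfile,
    ComboSample,
    DrugRecord,
    MonoSample,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "hill_response",
    "generate_combo_surface",
    "generate_dataset",
    "BASE_SMILES",
]

# Small valid molecules (alcohols, aromatics, amides, common scaffolds).
BASE_SMILES: tuple[str, ...] = (
    "CCO", "CC(=O)O", "c1ccccc1", "c1ccccc1O", "CC(=O)Nc1ccc(O)cc1",
    "CN1CCC[C@H]1c1cccnc1", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "C1CCCCC1", "c1ccc2ccccc2c1", "CCN(CC)CC", "CC(N)C(=O)O",
    "OCC(O)C(O)C(O)C(O)CO", "c1ccncc1", "CC(=O)OC1=CC=CC=C1C(=O)O",
    "NC(=O)c1ccccc1", "COc1ccccc1", "CCOC(=O)C", "CSCC", "OC(=O)c1ccccc1O",
    "C1CCNCC1", "Clc1ccccc1", "CC(C)(C)O", "N#Cc1ccccc1",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated screen."""

    n_drugs: int = 12
    n_cells: int = 6
    n_doses: int = 5
    dose_min: float = 0.01
    dose_max: float = 1.0
    ec50_log10_range: tuple[float, float] = (-2.0, 0.0)
    slope_range: tuple[float, float] = (0.5, 3.0)
    bump_amplitude_range: tuple[float, float] = (-0.3, 0.3)
    bump_width_range: tuple[float, float] = (0.5, 1.5)  # in log-dose units
    noise_sd: float = 0.05
    expression_length: int = 78
    n_latent: int = 4
    expression_noise_sd: float = 0.1
    ec50_latent_scale: float = 0.3  # decades of EC50 shift per latent unit
    percent_scale: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_cells, self.n_doses, self.n_latent) < 1:
            raise ValidationError("all counts must be positive")
        if self.n_drugs < 2:
            raise ValidationError("need at least two drugs to form a pair")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if not (0 < self.dose_min < self.dose_max):
            raise ValidationError("need 0 < dose_min < dose_max")

    @property
    def doses(self) -> np.ndarray:
        return np.geomspace(self.dose_min, self.dose_max, self.n_doses)


@dataclass
class GroundTruth:
    """Everything the generator drew, keyed for recovery tests."""

    doses: np.ndarray
    drug_slope: dict[str, float]
    # log10 EC50 per (drug, cell)
    log10_ec50: dict[tuple[str, str], float]
    # (amplitude, mu1, mu2, width) per (drug_lo, drug_hi, cell); mus in log-dose
    bump: dict[tuple[str, str, str], tuple[float, float, float, float]]
    # noise-free surface per (drug_lo, drug_hi, cell), shape (n_doses, n_doses)
    surface: dict[tuple[str, str, str], np.ndarray]
    latent: dict[str, np.ndarray]
    drug_loading: dict[str, np.ndarray]


@dataclass
class SyntheticDataset:
    combo: list[ComboSample]
    mono: list[MonoSample]
    drugs: list[DrugRecord]
    cells: dict[str, CellLineProfile]
    truth: GroundTruth


def hill_response(dose: float, ec50: float, slope: float):
    """Hill growth fraction ``1 / (1 + (dose/EC50)^slope)``.

    Strictly decreasing in dose; 0.5 at the EC50 for any slope. Accepts
    scalars or arrays of positive doses.
    """
    d = np.asarray(dose, dtype=np.float64)
    if np.any(d <= 0) or ec50 <= 0 or slope <= 0:
        raise ValidationError("dose, ec50 and slope must all be positive")
    out = 1.0 / (1.0 + (d / ec50) ** slope)
    return float(out) if np.isscalar(dose) or np.ndim(dose) == 0 else out


def _bump(log_r1, log_r2, amplitude, mu1, mu2, width) -> np.ndarray:
    return amplitude * np.exp(
        -((log_r1 - mu1) ** 2 + (log_r2 - mu2) ** 2) / (2.0 * width**2)
    )


def generate_combo_surface(
    drug1_id: str,
    drug2_id: str,
    cell_id: str,
    ec50_1: float,
    slope1: float,
    ec50_2: float,
    slope2: float,
    bump_params: tuple[float, float, float, float],
    doses1: np.ndarray,
    doses2: np.ndarray,
    noise_sd: float,
    seed: int,
    percent_scale: bool = False,
) -> tuple[list[ComboSample], np.ndarray]:
    """One full dose-response matrix: Bliss null + synergy bump + noise.

    Returns (samples in row-major grid order, noise-free surface).
    """
    g1 = hill_response(doses1, ec50_1, slope1)
    g2 = hill_response(doses2, ec50_2, slope2)
    a, mu1, mu2, w = bump_params
    log1, log2 = np.log(doses1), np.log(doses2)
    clean = np.outer(g1, g2) + _bump(log1[:, None], log2[None, :], a, mu1, mu2, w)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    scale = 100.0 if percent_scale else 1.0
    samples = [
        ComboSample(
            drug1_id, drug2_id, float(r1), float(r2), cell_id,
            float(noisy[i, j] * scale),
        )
        for i, r1 in enumerate(doses1)
        for j, r2 in enumerate(doses2)
    ]
    return samples, clean


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a mutually consistent four-table screen plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    doses = cfg.doses

    drug_ids = [f"D{i:02d}" for i in range(cfg.n_drugs)]
    cell_ids = [f"C{i:02d}" for i in range(cfg.n_cells)]

    smiles = []
    for i in range(cfg.n_drugs):
        base = BASE_SMILES[i % len(BASE_SMILES)]
        smiles.append(base + "C" * (i // len(BASE_SMILES)))  # chain-growth variants
    drugs = [DrugRecord(d, s) for d, s in zip(drug_ids, smiles)]

    # latent factors: drive both expression and per-cell EC50 shifts
    latent = {c: rng.normal(0.0, 1.0, size=cfg.n_latent) for c in cell_ids}
    loading = rng.normal(0.0, 1.0, size=(cfg.n_latent, cfg.expression_length))
    cells = {}
    for c in cell_ids:
        profile = latent[c] @ loading + rng.normal(
            0.0, cfg.expression_noise_sd, size=cfg.expression_length
        )
        cells[c] = CellLineProfile(c, tuple(map(float, profile)))

    lo10, hi10 = cfg.ec50_log10_range
    slope = {d: float(rng.uniform(*cfg.slope_range)) for d in drug_ids}
    base_log10 = {d: float(rng.uniform(lo10, hi10)) for d in drug_ids}
    drug_loading = {
        d: rng.normal(0.0, 1.0 / np.sqrt(cfg.n_latent), size=cfg.n_latent)
        for d in drug_ids
    }
    log10_ec50 = {}
    for d in drug_ids:
        for c in cell_ids:
            shift = cfg.ec50_latent_scale * float(drug_loading[d] @ latent[c])
            log10_ec50[(d, c)] = float(np.clip(base_log10[d] + shift, lo10, hi10))

    scale = 100.0 if cfg.percent_scale else 1.0
    mono: list[MonoSample] = []
    for d in drug_ids:
        for c in cell_ids:
            g = hill_response(doses, 10.0 ** log10_ec50[(d, c)], slope[d])
            g = np.clip(g + rng.normal(0.0, cfg.noise_sd, size=g.shape), 0.0, 1.0)
            mono.extend(
                MonoSample(d, float(r), c, float(v * scale))
                for r, v in zip(doses, g)
            )

    log_doses = np.log(doses)
    combo: list[ComboSample] = []
    bump: dict[tuple[str, str, str], tuple[float, float, float, float]] = {}
    surface: dict[tuple[str, str, str], np.ndarray] = {}
    for i in range(cfg.n_drugs):
        for j in range(i + 1, cfg.n_drugs):
            d1, d2 = drug_ids[i], drug_ids[j]
            for c in cell_ids:
                a = float(rng.uniform(*cfg.bump_amplitude_range))
                mu1 = float(rng.choice(log_doses))
                mu2 = float(rng.choice(log_doses))
                w = float(rng.uniform(*cfg.bump_width_range))
                bump[(d1, d2, c)] = (a, mu1, mu2, w)
                surf_seed = int(rng.integers(0, 2**31 - 1))
                samples, clean = generate_combo_surface(
                    d1, d2, c,
                    10.0 ** log10_ec50[(d1, c)], slope[d1],
                    10.0 ** log10_ec50[(d2, c)], slope[d2],
                    bump[(d1, d2, c)], doses, doses,
                    cfg.noise_sd, surf_seed, percent_scale=cfg.percent_scale,
                )
                combo.extend(samples)
                surface[(d1, d2, c)] = clean

    truth = GroundTruth(
        doses=doses,
        drug_slope=slope,
        log10_ec50=log10_ec50,
        bump=bump,
        surface=surface,
        latent=latent,
        drug_loading=drug_loading,
    )
    return SyntheticDataset(combo, mono, drugs, cells, truth)
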