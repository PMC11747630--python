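"""Synthetic coupled pelagic/benthic communities with known truth.

The generator emulates the statistical structure the analysis assumes:
a seasonal particulate-organic-carbon (POC) driver, module-structured
compositional count tables for two habitats, ranked taxonomy labels,
marker-gene-like sequences (~380 nt), and a configurable fraction of
"vertically exported" ASV pairs — pelagic carbon-module members whose
benthic counterparts carry a lag-smoothed copy of the pelagic signal
and a near-identical sequence. Everything is seeded and returns a
:class:`SyntheticTruth` record for parameter-recovery tests.

What it deliberately does not emulate: realistic 18S phylogenies,
mechanistic particle sinking, PCR/sequencing error profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .asv_io import AsvTable

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_environment",
    "generate_sequences",
    "generate_coupled_communities",
    "write_truth",
]

_DIVISIONS = (
    "Dinoflagellata",
    "Diatomea",
    "Radiolaria",
    "Cercozoa",
    "Chlorophyta",
    "Haptophyta",
    "Ciliophora",
    "Metazoa",
)
_BASES = np.array(list("ACGT"))


@dataclass
class GeneratorConfig:
    """Study-scale defaults for the coupled-community generator.

    The carbon module is module 1 in both habitats; its pelagic
    eigengene follows the POC flux and its benthic eigengene the
    lag-smoothed pelagic signal.
    """

    n_samples: int = 60          # per habitat (trap series / core set)
    n_modules: int = 4
    module_sizes: tuple[int, ...] = (30, 30, 30, 30)
    depth: int = 20000           # reads per sample
    member_eigengene_corr: float = 0.8
    pair_association: float = 0.55  # direct partner-pair coupling strength
    driver_loading: float = 0.8  # carbon eigengene ~ POC coupling
    coupling_fraction: float = 0.5
    seasonal_baseline: float = 10.0   # POC flux, mg C m-2 d-1
    seasonal_amplitude: float = 30.0
    seasonal_period: float = 12.0     # samples per seasonal cycle
    noise_sd: float = 2.0             # POC measurement noise
    ar_coef: float = 0.6              # AR(1) of module eigengenes
    abundance_sd: float = 1.0         # per-ASV base log-abundance spread
    seq_length: int = 380
    within_pair_mutation: float = 0.01
    within_genus_mutation: float = 0.02
    between_taxon_divergence: float = 0.25
    genus_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ValueError("coupling_fraction must lie in [0, 1]")
        for rate in (
            self.within_pair_mutation,
            self.within_genus_mutation,
            self.between_taxon_divergence,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("mutation rates must lie in [0, 1]")
        if min(self.module_sizes) < 1 or self.n_samples < 8 or self.depth < 1:
            raise ValueError("counts must be positive (n_samples >= 8)")
        if self.member_eigengene_corr**2 + self.pair_association**2 > 1.0:
            raise ValueError(
                "member_eigengene_corr^2 + pair_association^2 must be <= 1"
            )


@dataclass
class SyntheticTruth:
    """Planted structure: module labels, driver loadings, coupled pairs."""

    module_labels: dict[str, dict[str, int]]       # habitat -> asv -> module
    carbon_module: int
    driver_loadings: dict[str, float]              # habitat -> loading
    coupled_pairs: list[tuple[str, str]] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)


def generate_environment(
    n_times: int, config: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Seasonal environmental metadata for one habitat.

    POC flux is a rectified sinusoid (bloom-export pulses) plus
    Gaussian noise; a season index (0-3) and a longitude column are
    included.
    """
    if n_times < 8:
        raise ValueError("need at least 8 time points")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = np.arange(n_times)
    clean = config.seasonal_baseline + config.seasonal_amplitude * np.maximum(
        0.0, np.sin(2 * np.pi * t / config.seasonal_period)
    )
    poc = clean + rng.normal(0.0, config.noise_sd, n_times)
    season = ((t % config.seasonal_period) / config.seasonal_period * 4).astype(int)
    longitude = 116.0 + rng.normal(0.0, 0.5, n_times)
    return pd.DataFrame(
        {
            "poc_flux": poc,
            "poc_flux_clean": clean,
            "season": season,
            "longitude": longitude,
        },
        index=[f"T{i:03d}" for i in t],
    )


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability ``rate`` (to a
    different base)."""
    seq = seq.copy()
    hit = rng.random(seq.size) < rate
    if hit.any():
        shifts = rng.integers(1, 4, hit.sum())
        base_idx = np.searchsorted(_BASES, seq[hit])
        seq[hit] = _BASES[(base_idx + shifts) % 4]
    return seq


def generate_sequences(
    taxonomy: pd.DataFrame, config: GeneratorConfig, seed: int | None = None
) -> dict[str, str]:
    """Marker-fragment-like sequences respecting the taxonomy.

    One random root per division, a genus reference mutated from it at
    the between-taxon divergence, and per-ASV sequences mutated from
    the genus reference at the (low) within-genus rate.
    """
    if config.seq_length < 100:
        raise ValueError("sequence length must be >= 100")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    roots: dict[str, np.ndarray] = {}
    genus_refs: dict[str, np.ndarray] = {}
    out: dict[str, str] = {}
    for asv in taxonomy.index:
        division = str(taxonomy.at[asv, "division"])
        genus = str(taxonomy.at[asv, "genus"])
        if division not in roots:
            roots[division] = rng.choice(_BASES, config.seq_length)
        if genus not in genus_refs:
            genus_refs[genus] = _mutate(
                roots[division], config.between_taxon_divergence, rng
            )
        out[asv] = "".join(_mutate(genus_refs[genus], config.within_genus_mutation, rng))
    return out


def _taxonomy_for(
    prefix: str, labels: pd.Series, config: GeneratorConfig
) -> pd.DataFrame:
    """Ranked lineage per ASV: two divisions per module, genera of
    ``genus_size`` consecutive members."""
    rows = {}
    for asv in labels.index:
        m = int(labels[asv])
        ordinal = int(asv.split("_")[-1])
        div = _DIVISIONS[(2 * (m - 1) + (ordinal % 2)) % len(_DIVISIONS)]
        genus_id = ordinal // config.genus_size
        rows[asv] = {
            "division": div,
            "class": f"{div}_class",
            "order": f"{div}_order_{m}",
            "family": f"{div}_family_{m}",
            "genus": f"{div}_genus_{genus_id}",
            "species": f"{div}_sp_{ordinal}",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _eigengenes(
    drivers: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Module eigengenes: carbon module follows the driver, the rest
    are independent AR(1) series; all standardized."""
    n = drivers.size
    eig = np.zeros((config.n_modules, n))
    lam = config.driver_loading
    for m in range(config.n_modules):
        ar = np.zeros(n)
        eps = rng.normal(0.0, 1.0, n)
        for t in range(n):
            ar[t] = (config.ar_coef * ar[t - 1] if t else 0.0) + eps[t]
        ar = (ar - ar.mean()) / ar.std()
        if m == 0:
            z = (drivers - drivers.mean()) / drivers.std()
            e = lam * z + np.sqrt(1 - lam**2) * ar
        else:
            e = ar
        eig[m] = (e - e.mean()) / e.std()
    return eig


def _latent_profiles(
    labels: pd.Series,
    eig: np.ndarray,
    base: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    preset_pairs: dict[tuple[int, int], np.ndarray] | None = None,
) -> tuple[np.ndarray, dict[tuple[int, int], np.ndarray]]:
    """Per-ASV latent log-abundance: eigengene loading + a direct
    partner-pair association + idiosyncratic noise.

    Consecutive members of a module form disjoint partner pairs sharing
    an extra latent factor (weight ``pair_association``) — the direct
    ecological associations a conditional-independence network detects
    over and above the shared environmental driver. ``preset_pairs``
    lets a pair (module, pair-index) reuse an externally supplied
    factor (the export-coupled case); the pair factors used are
    returned so the coupled habitat can inherit them.
    """
    n = eig.shape[1]
    lam = config.member_eigengene_corr
    gam = config.pair_association
    resid = np.sqrt(max(1.0 - lam**2 - gam**2, 0.0))
    latent = np.zeros((n, len(labels)))
    positions = {a: i for i, a in enumerate(labels.index)}
    preset_pairs = preset_pairs or {}
    pair_factors: dict[tuple[int, int], np.ndarray] = {}
    for m in sorted(labels.unique()):
        members = [a for a in labels.index if labels[a] == m]
        for k in range(0, len(members) - 1, 2):
            u = preset_pairs.get((m, k // 2))
            if u is None:
                u = rng.normal(0.0, 1.0, n)
            pair_factors[(m, k // 2)] = u
            for a in (members[k], members[k + 1]):
                j = positions[a]
                noise = rng.normal(0.0, 1.0, n)
                latent[:, j] = (
                    base[j] + lam * eig[m - 1] + gam * u + resid * noise
                )
        if len(members) % 2:  # unpaired last member
            j = positions[members[-1]]
            noise = rng.normal(0.0, 1.0, n)
            latent[:, j] = (
                base[j] + lam * eig[m - 1] + np.sqrt(1.0 - lam**2) * noise
            )
    return latent, pair_factors


def _counts_from_latent(
    latent: np.ndarray,
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    probs = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, p) for p in probs])


def generate_coupled_communities(
    config: GeneratorConfig | None = None,
) -> tuple[AsvTable, AsvTable, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the full two-habitat study: tables, metadata, truth.

    Returns ``(pelagic, benthic, meta_pelagic, meta_benthic, truth)``.
    A ``coupling_fraction`` of the pelagic carbon-module ASVs get
    benthic counterparts whose latent signal is the lag-1-smoothed
    pelagic eigengene and whose sequence differs only by the
    within-pair mutation rate; all other benthic ASVs are
    habitat-specific.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    meta_p = generate_environment(n, config, seed=config.seed + 10)
    eig_p = _eigengenes(meta_p["poc_flux"].to_numpy(), config, rng)

    # --- pelagic table -----------------------------------------------------
    p_labels = {}
    asv = 0
    for m, size in enumerate(config.module_sizes, start=1):
        for _ in range(size):
            p_labels[f"P_ASV_{asv:04d}"] = m
            asv += 1
    p_labels = pd.Series(p_labels)
    base_p = rng.normal(0.0, config.abundance_sd, len(p_labels))
    latent_p, pair_factors_p = _latent_profiles(p_labels, eig_p, base_p, config, rng)
    counts_p = _counts_from_latent(latent_p, config.depth, rng)

    tax_p = _taxonomy_for("P", p_labels, config)
    seqs_p = generate_sequences(tax_p, config, seed=config.seed + 20)

    # --- benthic table -----------------------------------------------------
    # lag-1 smoothing of the pelagic carbon eigengene mimics export delay
    e1 = eig_p[0]
    lagged = np.empty_like(e1)
    lagged[0] = e1[0]
    lagged[1:] = 0.5 * (e1[:-1] + e1[1:])
    lagged = (lagged - lagged.mean()) / lagged.std()

    meta_b = generate_environment(n, config, seed=config.seed + 30)
    meta_b = meta_b.rename(
        columns={"poc_flux": "unrelated_flux", "poc_flux_clean": "unrelated_flux_clean"}
    )
    meta_b.index = [f"S{i:03d}" for i in range(n)]
    corg_noise = rng.normal(0.0, 0.4, n)
    meta_b["longitude"] = 110.0 + np.linspace(0.0, 10.0, n) + rng.normal(0.0, 0.2, n)

    eig_b = _eigengenes(rng.normal(0.0, 1.0, n), config, rng)
    eig_b[0] = lagged  # benthic carbon module carries the exported signal
    meta_b["corg"] = 1.0 + 0.35 * lagged + corg_noise  # sediment Corg, %

    b_labels = {}
    asv = 0
    for m, size in enumerate(config.module_sizes, start=1):
        for _ in range(size):
            b_labels[f"B_ASV_{asv:04d}"] = m
            asv += 1
    b_labels = pd.Series(b_labels)

    carbon_p = [a for a in p_labels.index if p_labels[a] == 1]
    carbon_b = [a for a in b_labels.index if b_labels[a] == 1]
    n_coupled = int(round(config.coupling_fraction * min(len(carbon_p), len(carbon_b))))
    coupled_pairs = list(zip(carbon_p[:n_coupled], carbon_b[:n_coupled]))

    tax_b = _taxonomy_for("B", b_labels, config)
    seqs_b = generate_sequences(tax_b, config, seed=config.seed + 40)
    seq_rng = np.random.default_rng(config.seed + 50)
    for pa, ba in coupled_pairs:
        # exported counterpart: same lineage, near-identical sequence
        tax_b.loc[ba] = tax_p.loc[pa]
        seqs_b[ba] = "".join(
            _mutate(np.array(list(seqs_p[pa])), config.within_pair_mutation, seq_rng)
        )

    # export-coupled pairs whose two partners are both exported keep
    # their direct association on the seafloor: the benthic pair factor
    # is the lag-smoothed pelagic one
    def _lag_smooth(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        out[0] = x[0]
        out[1:] = 0.5 * (x[:-1] + x[1:])
        return (out - out.mean()) / out.std()

    preset_pairs_b = {
        (1, k): _lag_smooth(pair_factors_p[(1, k)])
        for k in range(n_coupled // 2)
        if (1, k) in pair_factors_p
    }
    base_b = rng.normal(0.0, config.abundance_sd, len(b_labels))
    latent_b, _ = _latent_profiles(
        b_labels, eig_b, base_b, config, rng, preset_pairs=preset_pairs_b
    )
    counts_b = _counts_from_latent(latent_b, config.depth, rng)

    pelagic = AsvTable(
        pd.DataFrame(counts_p, index=meta_p.index, columns=p_labels.index),
        tax_p,
        seqs_p,
    )
    benthic = AsvTable(
        pd.DataFrame(counts_b, index=meta_b.index, columns=b_labels.index),
        tax_b,
        seqs_b,
    )
    truth = SyntheticTruth(
        module_labels={
            "pelagic": p_labels.to_dict(),
            "benthic": b_labels.to_dict(),
        },
        carbon_module=1,
        driver_loadings={
            "pelagic": config.driver_loading,
            "benthic": 0.35,
        },
        coupled_pairs=coupled_pairs,
        sequences={**seqs_p, **seqs_b},
    )
    return pelagic, benthic, meta_p, meta_b, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialise the planted truth (minus sequences) as JSON."""
    record = asdict(truth)
    record["coupled_pairs"] = [list(p) for p in truth.coupled_pairs]
    record.pop("sequences")
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))
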