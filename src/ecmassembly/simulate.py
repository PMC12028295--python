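"""Synthetic EcM community generator with known assembly regime.

Emulates the study design — 6 tree species (3 conifer, 3 broadleaf) x 2
developmental stages x 10 replicate root samples, ~23k reads per sample —
under two generative regimes with known ground truth:

* **neutral**: each sample's composition is a Dirichlet draw around the
  metacommunity with concentration ``N_T * m_sim * p`` (the stationary
  sampling law of a dispersal-coupled local community; larger ``m_sim``
  couples samples more tightly to the regional pool), followed by multinomial
  read sampling.
* **niche**: sample composition is deterministic per host,
  ``p_i * affinity[i, host] ** filter_strength`` renormalized, followed by
  multinomial read sampling.  Heterogeneous host affinities decouple
  occupancy from mean abundance within mixed-host groups.

By default juvenile groups are generated under the niche regime and adult
groups under the neutral regime, so the downstream occupancy fit has a known
qualitative answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import AsvTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_metacommunity",
    "simulate_neutral_group",
    "simulate_niche_group",
    "generate_study",
]

# plausible genus labels; EcM list drawn from common ectomycorrhizal genera,
# decoys from ubiquitous root-associated saprotrophs/molds
ECM_GENERA = (
    "Russula", "Tomentella", "Inocybe", "Sebacina", "Lactarius", "Amphinema",
    "Cenococcum", "Piloderma", "Tuber", "Wilcoxina", "Suillus", "Hebeloma",
    "Tylospora", "Cortinarius", "Laccaria", "Rhodoscypha", "Pseudotomentella",
)
NON_ECM_GENERA = (
    "Mortierella", "Trichoderma", "Penicillium", "Fusarium", "Cladosporium",
    "Aspergillus", "Mycena", "Umbelopsis",
)


@dataclass
class SyntheticConfig:
    """Parameters of the simulated study.

    Defaults reproduce the study scale: 2 host types x 3 species x 2 stages
    x 10 replicates = 120 samples at 23,167 reads each, 300 EcM ASVs in a
    lognormal (mu=0, sigma=1.5) metacommunity plus 20% non-EcM decoys.
    """

    n_species_per_type: int = 3
    n_replicates: int = 10
    depth: int = 23_167
    n_asvs: int = 300
    meta_distribution: str = "lognormal"
    meta_sigma: float = 1.5
    meta_logseries_theta: float = 0.998
    regime_by_stage: dict = field(
        default_factory=lambda: {"juvenile": "niche", "adult": "neutral"}
    )
    m_sim: float = 0.5
    filter_strength: float = 2.0
    affinity_sparsity: float = 0.5
    affinity_sigma: float = 0.5
    decoy_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_asvs < 2:
            raise ValueError("n_asvs must be >= 2")
        if not (0 < self.m_sim <= 1):
            raise ValueError("m_sim must be in (0, 1]")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be >= 0")
        for regime in self.regime_by_stage.values():
            if regime not in ("neutral", "niche"):
                raise ValueError(f"unknown regime {regime!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one generated study."""

    regime_by_group: dict
    m_sim: float
    filter_strength: float
    affinity: pd.DataFrame  # ASV x host-species weights (niche regime)
    metacommunity: pd.Series  # ASV -> regional proportion
    ecm_asvs: list[str]

    def to_dict(self) -> dict:
        return {
            "regime_by_group": self.regime_by_group,
            "m_sim": self.m_sim,
            "filter_strength": self.filter_strength,
            "affinity": self.affinity.to_dict(),
            "metacommunity": self.metacommunity.to_dict(),
            "ecm_asvs": list(self.ecm_asvs),
        }


def simulate_metacommunity(
    n_asvs: int,
    meta_distribution: str = "lognormal",
    seed=None,
    *,
    sigma: float = 1.5,
    theta: float = 0.998,
) -> np.ndarray:
    """Draw a long-tailed metacommunity relative-abundance vector.

    ``lognormal`` draws abundances LogNormal(0, sigma); ``logseries`` draws
    Fisher log-series counts with parameter ``theta``.  Returned proportions
    sum to 1.
    """
    if n_asvs < 2:
        raise ValueError("n_asvs must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if meta_distribution == "lognormal":
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_asvs)
    elif meta_distribution == "logseries":
        if not (0 < theta < 1):
            raise ValueError("logseries theta must be in (0, 1)")
        raw = rng.logseries(theta, size=n_asvs).astype(float)
    else:
        raise ValueError(f"unknown meta_distribution {meta_distribution!r}")
    return raw / raw.sum()


def simulate_neutral_group(
    p: np.ndarray,
    n_samples: int,
    depth: int,
    m_sim: float,
    seed=None,
    *,
    sample_ids: list[str] | None = None,
    asv_ids: list[str] | None = None,
) -> AsvTable:
    """Dispersal-coupled neutral sampling of one host group.

    Each sample: proportions ~ Dirichlet(N_T * m_sim * p) with N_T = depth,
    then counts ~ Multinomial(depth, proportions).
    """
    p = np.asarray(p, float)
    if not (0 < m_sim <= 1):
        raise ValueError("m_sim must be in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    alpha = depth * m_sim * p
    counts = np.zeros((len(p), n_samples), dtype=np.int64)
    for j in range(n_samples):
        props = rng.dirichlet(alpha)
        counts[:, j] = rng.multinomial(depth, props)
    asv_ids = asv_ids or [f"ASV{i+1}" for i in range(len(p))]
    sample_ids = sample_ids or [f"S{j+1}" for j in range(n_samples)]
    return AsvTable(counts, asv_ids, sample_ids)


def simulate_niche_group(
    p: np.ndarray,
    affinity: np.ndarray,
    filter_strength: float,
    n_samples: int,
    depth: int,
    seed=None,
    *,
    sample_ids: list[str] | None = None,
    asv_ids: list[str] | None = None,
) -> AsvTable:
    """Host-filtered (deterministic) sampling of one group.

    ``affinity`` is (n_asvs,) for a single host or (n_asvs, n_hosts) for a
    mixed group with ``n_samples`` replicates per host.  Sample proportions
    are ``p_i * affinity_i ** filter_strength`` renormalized (with 0**0 = 1,
    so ``filter_strength = 0`` reduces to plain multinomial sampling from p),
    then counts ~ Multinomial(depth).
    """
    p = np.asarray(p, float)
    affinity = np.asarray(affinity, float)
    if affinity.ndim == 1:
        affinity = affinity[:, None]
    if affinity.shape[0] != len(p):
        raise ValueError("affinity must have one row per ASV")
    if (affinity < 0).any():
        raise ValueError("affinity weights must be >= 0")
    if filter_strength < 0:
        raise ValueError("filter_strength must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_hosts = affinity.shape[1]
    with np.errstate(divide="ignore"):
        weight = np.where(
            filter_strength == 0, np.ones_like(affinity), affinity ** filter_strength
        )
    counts = np.zeros((len(p), n_hosts * n_samples), dtype=np.int64)
    for h in range(n_hosts):
        w = p * weight[:, h]
        if w.sum() <= 0:
            raise ValueError(f"host {h}: all filtered proportions are zero")
        w = w / w.sum()
        for j in range(n_samples):
            counts[:, h * n_samples + j] = rng.multinomial(depth, w)
    asv_ids = asv_ids or [f"ASV{i+1}" for i in range(len(p))]
    sample_ids = sample_ids or [
        f"H{h+1}.S{j+1}" for h in range(n_hosts) for j in range(n_samples)
    ]
    return AsvTable(counts, asv_ids, sample_ids)


def generate_study(
    config: SyntheticConfig,
) -> tuple[AsvTable, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a full synthetic study: counts, metadata, taxonomy, truth.

    Juvenile groups follow ``regime_by_stage['juvenile']`` (niche by
    default), adult groups the neutral regime.  A ``decoy_fraction`` of extra
    non-EcM ASVs is mixed into the metacommunity so the guild filter is
    exercised end-to-end.
    """
    rng = np.random.default_rng(config.seed)
    n_decoys = int(round(config.decoy_fraction * config.n_asvs))
    n_total = config.n_asvs + n_decoys
    p = simulate_metacommunity(
        n_total,
        config.meta_distribution,
        rng,
        sigma=config.meta_sigma,
        theta=config.meta_logseries_theta,
    )
    asv_ids = [f"ASV{i+1:04d}" for i in range(n_total)]
    is_ecm = np.ones(n_total, bool)
    if n_decoys:
        decoy_idx = rng.choice(n_total, size=n_decoys, replace=False)
        is_ecm[decoy_idx] = False

    species = [
        f"{ht}_sp{i+1}"
        for ht in ("Conifer", "Broadleaf")
        for i in range(config.n_species_per_type)
    ]
    host_type = {
        sp: ("conifer" if sp.startswith("Conifer") else "broadleaf") for sp in species
    }
    # per-host affinities: sparse host specialism (zero affinity to a random
    # subset of hosts) times a moderate lognormal intensity; filter_strength
    # amplifies the intensity part
    n_hosts = len(species)
    present = rng.random((n_total, n_hosts)) >= config.affinity_sparsity
    no_host = ~present.any(axis=1)
    present[no_host, rng.integers(0, n_hosts, size=int(no_host.sum()))] = True
    affinity = present * rng.lognormal(0.0, config.affinity_sigma, (n_total, n_hosts))
    affinity_df = pd.DataFrame(affinity, index=asv_ids, columns=species)

    blocks, meta_rows = [], []
    regime_by_group: dict[str, str] = {}
    for stage in ("juvenile", "adult"):
        regime = config.regime_by_stage.get(stage, "neutral")
        for s_idx, sp in enumerate(species):
            sids = [
                f"{sp}.{stage}.r{r+1:02d}" for r in range(config.n_replicates)
            ]
            if regime == "neutral":
                block = simulate_neutral_group(
                    p, config.n_replicates, config.depth, config.m_sim, rng,
                    sample_ids=sids, asv_ids=asv_ids,
                )
            else:
                block = simulate_niche_group(
                    p, affinity[:, s_idx], config.filter_strength,
                    config.n_replicates, config.depth, rng,
                    sample_ids=sids, asv_ids=asv_ids,
                )
            blocks.append(block)
            regime_by_group[f"{host_type[sp]}-{stage}"] = regime
            for r, sid in enumerate(sids):
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "host_species": sp,
                        "host_type": host_type[sp],
                        "stage": stage,
                        "replicate": r + 1,
                    }
                )

    counts = np.hstack([b.counts for b in blocks])
    sample_ids = [s for b in blocks for s in b.sample_ids]
    table = AsvTable(counts, asv_ids, sample_ids)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)

    genera = np.where(
        is_ecm,
        np.array(ECM_GENERA)[rng.integers(0, len(ECM_GENERA), n_total)],
        np.array(NON_ECM_GENERA)[rng.integers(0, len(NON_ECM_GENERA), n_total)],
    )
    phyla = np.where(is_ecm, "Basidiomycota", "Ascomycota")
    taxonomy = pd.DataFrame(
        {
            "asv_id": asv_ids,
            "lineage": [
                f"k__Fungi;p__{ph};c__;o__;f__;g__{g};s__{g}_sp"
                for ph, g in zip(phyla, genera)
            ],
            "genus": genera,
            "is_ecm": is_ecm,
        }
    ).set_index("asv_id", drop=False)

    truth = SyntheticTruth(
        regime_by_group=regime_by_group,
        m_sim=config.m_sim,
        filter_strength=config.filter_strength,
        affinity=affinity_df,
        metacommunity=pd.Series(p, index=asv_ids),
        ecm_asvs=[a for a, e in zip(asv_ids, is_ecm) if e],
    )
    return table, metadata, taxonomy, truth
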