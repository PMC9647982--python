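"""Synthetic pedigreed two-line broiler cohorts with known genetic architecture.

The generator emulates the design of a divergent-line feed-efficiency study:
two closed lines ("lean" = high feed efficiency, "fat" = low), a shallow
nested-mating pedigree (each sire mated to several dams, several offspring per
dam), and per-bird phenotypes (BW4, BW7, total feed intake over the 4-7 week
test) plus positive- and negative-ion-mode metabolite intensity panels.

Genetic model.  Each metabolite and a latent feed-intake deviation carry
additive genetic effects a ~ N(0, A (x) G): founders are drawn N(0, G),
non-founders are the parental mean plus a Mendelian-sampling deviation with
covariance G/2 (the non-inbred approximation; the simulated pedigrees are
shallow and non-inbred by construction, and the inbreeding-aware component
under test is the A-matrix builder, not the simulator).  Feed intake is
generated as b0 + b1*MMBW + b2*BWG + line shift + deviation, so the residual
feed intake recovered by the downstream OLS fit equals the deviation up to the
(vanishing) projection on the predictors, making configured metabolite-RFI
genetic correlations exact at the generative level.  Keys (feature, "fcr")
are mapped onto the same intake deviation, so FCR correlations are
approximate.  Body weights carry line/sex/environment effects only.

Mating scheme.  Per line and generation, previous-generation animals in id
order are partitioned into blocks of (1 + dams_per_sire); the first animal of
each complete block is the sire, the rest are its dams, leftovers stay unmated.
Sex follows breeding role; never-mated animals alternate male/female.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InputError, ModelError
from .pedigree import UNKNOWN_PARENT, Pedigree
from .preprocess import MetaboliteMatrix

__all__ = [
    "SimulationConfig",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_cohort",
]

FE_INDEX = "rfi"  # the latent intake-deviation trait name in G


@dataclass
class SimulationConfig:
    """Study-design and genetic-architecture knobs for the synthetic cohort.

    Defaults emulate a 441-bird two-line cohort with nested half-sib families,
    284 positive-mode and 272 negative-mode annotated metabolites.  Intensity
    units are arbitrary; weights and intake are grams.
    """

    n_founders_per_line: int = 24
    n_generations: int = 1
    dams_per_sire: int = 3
    offspring_per_dam: int = 13
    n_phenotyped: int | None = 441  # cap on phenotyped birds; None = no cap
    phenotype_generations: str = "last"  # "last" or "all"

    n_metabolites_pos: int = 284
    n_metabolites_neg: int = 272
    true_h2: dict = field(default_factory=dict)  # feature -> h2 (others default_h2)
    default_h2: float = 0.15
    true_rg: dict = field(default_factory=dict)  # (feature, "rfi"|"fcr") -> r_g
    line_effect: dict = field(default_factory=dict)  # feature -> fat-line shift
    sex_effect: dict = field(default_factory=dict)  # feature -> male shift
    baseline_mean: float = 1000.0  # intensity units
    residual_sd: float = 150.0  # environmental SD of a metabolite, intensity units

    # feed-intake deviation (the generative RFI), grams
    fe_h2: float = 0.35
    fe_sd: float = 150.0  # phenotypic SD of the deviation
    fe_line_shift: float = 60.0  # extra intake of the fat line

    # body weights (grams) and the intake regression truth
    bw4_mean: float = 600.0
    bw4_sd: float = 40.0
    bw7_mean: float = 1900.0
    bw7_sd: float = 110.0
    bw_line_shift: float = 60.0  # fat line heavier at 7 wk
    bw_sex_shift: float = 120.0  # males heavier at 7 wk
    b0: float = 100.0
    b1: float = 4.0  # g per g^0.75
    b2: float = 1.65  # g per g of gain

    intensity_floor_frac: float = 1e-6  # floor as a fraction of baseline_mean
    seed: int = 20220441

    def __post_init__(self):
        for name in ("n_founders_per_line", "dams_per_sire", "offspring_per_dam"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if self.phenotype_generations not in ("last", "all"):
            raise ConfigurationError("phenotype_generations must be 'last' or 'all'")
        for feat, h2 in {**self.true_h2, "<default>": self.default_h2, "<fe>": self.fe_h2}.items():
            if not 0.0 <= h2 <= 1.0:
                raise ConfigurationError(f"h2 for {feat!r} must be in [0, 1], got {h2}")
        seen = set()
        for key, rg in self.true_rg.items():
            feat, index = key
            if index not in ("rfi", "fcr"):
                raise ConfigurationError(f"r_g index must be 'rfi' or 'fcr', got {index!r}")
            if feat in seen:
                raise ConfigurationError(
                    f"feature {feat!r} has r_g configured against both indices; "
                    "both map onto the same intake deviation, configure one"
                )
            seen.add(feat)
            if not -1.0 <= rg <= 1.0:
                raise ConfigurationError(f"r_g for {key} must be in [-1, 1], got {rg}")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be positive")
        if self.residual_sd < 0 or self.fe_sd < 0:
            raise ConfigurationError("standard deviations must be nonnegative")
        # PSD of the implied genetic correlation structure: metabolites are
        # mutually independent, each correlated only with the intake deviation,
        # so the correlation matrix is PSD iff sum of r_g^2 <= 1.
        total = sum(rg**2 for rg in self.true_rg.values())
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"configured r_g values imply a non-PSD genetic covariance "
                f"(sum of squares {total:.3f} > 1)"
            )

    # -- derived feature bookkeeping -------------------------------------
    def feature_ids(self, ion_mode: str) -> list[str]:
        if ion_mode == "positive":
            return [f"P{i + 1:04d}" for i in range(self.n_metabolites_pos)]
        return [f"N{i + 1:04d}" for i in range(self.n_metabolites_neg)]

    def all_features(self) -> list[str]:
        return self.feature_ids("positive") + self.feature_ids("negative")

    def h2_of(self, feature: str) -> float:
        return float(self.true_h2.get(feature, self.default_h2))

    def rg_of(self, feature: str) -> float:
        for index in ("rfi", "fcr"):
            if (feature, index) in self.true_rg:
                return float(self.true_rg[(feature, index)])
        return 0.0

    def to_yaml(self, path) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
        }
        data["true_rg"] = {f"{feat}:{idx}": v for (feat, idx), v in self.true_rg.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "true_rg" in data:
            parsed = {}
            for key, v in data["true_rg"].items():
                feat, idx = key.rsplit(":", 1)
                parsed[(feat, idx)] = v
            data["true_rg"] = parsed
        return cls(**data)


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Deterministic two-line nested-mating pedigree.

    Founders have both parents unknown; every non-founder's sire and dam come
    from the previous generation of the same line.  The returned frame carries
    extra ``line`` and ``sex`` columns used by the phenotype simulator.
    """
    rows = []
    next_id = 1
    per_line_current: dict[str, list[dict]] = {}
    for line in ("lean", "fat"):
        founders = []
        for _ in range(config.n_founders_per_line):
            rec = {
                "animal": str(next_id),
                "sire": UNKNOWN_PARENT,
                "dam": UNKNOWN_PARENT,
                "generation": 0,
                "line": line,
                "sex": None,
                "mated": False,
            }
            founders.append(rec)
            next_id += 1
        per_line_current[line] = founders
        rows.extend(founders)

    for gen in range(1, config.n_generations + 1):
        for line in ("lean", "fat"):
            parents = per_line_current[line]
            block = 1 + config.dams_per_sire
            offspring = []
            n_blocks = len(parents) // block
            for bi in range(n_blocks):
                group = parents[bi * block : (bi + 1) * block]
                sire = group[0]
                sire["sex"] = "male"
                sire["mated"] = True
                for dam in group[1:]:
                    dam["sex"] = "female"
                    dam["mated"] = True
                    for k in range(config.offspring_per_dam):
                        rec = {
                            "animal": str(next_id),
                            "sire": sire["animal"],
                            "dam": dam["animal"],
                            "generation": gen,
                            "line": line,
                            "sex": None,
                            "mated": False,
                        }
                        offspring.append(rec)
                        next_id += 1
            per_line_current[line] = offspring
            rows.extend(offspring)

    # sex for animals never used as parents: alternate within line
    for line in ("lean", "fat"):
        toggle = 0
        for rec in rows:
            if rec["line"] == line and rec["sex"] is None:
                rec["sex"] = "male" if toggle % 2 == 0 else "female"
                toggle += 1

    df = pd.DataFrame(rows)[["animal", "sire", "dam", "generation", "line", "sex"]]
    return Pedigree(df)


def _psd_factor(G: np.ndarray) -> np.ndarray:
    """Factor L with L L' = G for a PSD matrix (eigh-based, tolerates zeros)."""
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=1e-10):
        raise ModelError("G must be symmetric")
    vals, vecs = np.linalg.eigh(G)
    if vals.min() < -1e-8 * max(1.0, abs(vals).max()):
        raise ModelError(f"G is not positive semi-definite (min eigenvalue {vals.min():.3g})")
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_breeding_values(pedigree: Pedigree, G: np.ndarray, seed: int) -> np.ndarray:
    """Additive genetic values a ~ N(0, A (x) G) by gene dropping.

    Founders are N(0, G); non-founders are the parental mean plus a
    Mendelian-sampling deviation N(0, G/2).  Returns (n_animals, n_traits) in
    pedigree row order.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    L = _psd_factor(G)
    L_half = L / np.sqrt(2.0)
    n = len(pedigree)
    k = G.shape[0]
    parents = pedigree.parent_indices()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k))
    bv = np.empty((n, k))
    for i in range(n):
        s, d = parents[i]
        if s < 0 and d < 0:
            bv[i] = L @ z[i]
        else:
            mean = np.zeros(k)
            if s >= 0:
                mean += bv[s]
            if d >= 0:
                mean += bv[d]
            bv[i] = 0.5 * mean + L_half @ z[i]
    return bv


def _genetic_covariance(config: SimulationConfig) -> tuple[np.ndarray, list[str]]:
    """Arrow-shaped G over (metabolites ..., intake deviation)."""
    features = config.all_features()
    h2 = np.array([config.h2_of(f) for f in features])
    h2c = np.minimum(h2, 1.0 - 1e-6)
    sig_a = config.residual_sd * np.sqrt(h2c / (1.0 - h2c))
    sig_a_fe = config.fe_sd * np.sqrt(config.fe_h2)
    k = len(features) + 1
    G = np.zeros((k, k))
    G[np.arange(len(features)), np.arange(len(features))] = sig_a**2
    G[-1, -1] = sig_a_fe**2
    for j, f in enumerate(features):
        rg = config.rg_of(f)
        if rg:
            G[j, -1] = G[-1, j] = rg * sig_a[j] * sig_a_fe
    return G, features


def simulate_phenotypes(pedigree: Pedigree, config: SimulationConfig):
    """Phenotype table plus positive/negative metabolite matrices.

    Returns
    -------
    phenotypes : pandas.DataFrame
        ``bird_id, line, sex, bw4_g, bw7_g, fi_g`` for the phenotyped birds.
    pos, neg : MetaboliteMatrix
        Raw (un-normalized) intensity panels for the same birds.
    """
    if "line" not in pedigree.df.columns or "sex" not in pedigree.df.columns:
        raise InputError("pedigree lacks line/sex metadata; use simulate_pedigree")
    G, features = _genetic_covariance(config)
    ss = np.random.SeedSequence(config.seed)
    seed_bv, seed_env = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    bv = simulate_breeding_values(pedigree, G, seed_bv)

    df = pedigree.df
    if config.phenotype_generations == "last":
        last = df["generation"].max()
        mask = (df["generation"] == last).to_numpy()
    else:
        mask = np.ones(len(df), dtype=bool)
    idx = np.flatnonzero(mask)
    if config.n_phenotyped is not None:
        idx = idx[: config.n_phenotyped]
    sub = df.iloc[idx]
    n = len(sub)
    if n == 0:
        raise ConfigurationError("no birds to phenotype under this configuration")
    fat = (sub["line"] == "fat").to_numpy(dtype=float)
    male = (sub["sex"] == "male").to_numpy(dtype=float)

    rng = np.random.default_rng(seed_env)
    bw4 = config.bw4_mean + 0.3 * config.bw_line_shift * fat + 0.3 * config.bw_sex_shift * male
    bw4 = bw4 + rng.standard_normal(n) * config.bw4_sd
    bw7 = config.bw7_mean + config.bw_line_shift * fat + config.bw_sex_shift * male
    bw7 = bw7 + rng.standard_normal(n) * config.bw7_sd
    bw7 = np.maximum(bw7, bw4 + 1.0)  # the test window always shows gain
    bwg = bw7 - bw4
    mmbw = ((bw4 + bw7) / 2.0) ** 0.75

    fe_dev_a = bv[idx, -1]
    fe_dev_e = rng.standard_normal(n) * (config.fe_sd * np.sqrt(1.0 - config.fe_h2))
    fi = (
        config.b0
        + config.b1 * mmbw
        + config.b2 * bwg
        + config.fe_line_shift * fat
        + fe_dev_a
        + fe_dev_e
    )
    phenotypes = pd.DataFrame(
        {
            "bird_id": sub["animal"].to_numpy(),
            "line": sub["line"].to_numpy(),
            "sex": sub["sex"].to_numpy(),
            "bw4_g": bw4,
            "bw7_g": bw7,
            "fi_g": fi,
        }
    )

    floor = config.intensity_floor_frac * config.baseline_mean
    values = np.empty((n, len(features)))
    for j, f in enumerate(features):
        noise = rng.standard_normal(n) * config.residual_sd
        values[:, j] = (
            config.baseline_mean
            + config.line_effect.get(f, 0.0) * fat
            + config.sex_effect.get(f, 0.0) * male
            + bv[idx, j]
            + noise
        )
    values = np.maximum(values, floor)

    birds = sub["animal"].astype(str).tolist()
    n_pos = config.n_metabolites_pos
    matrices = {}
    for mode, sl in (("positive", slice(0, n_pos)), ("negative", slice(n_pos, None))):
        feats = features[sl]
        matrices[mode] = MetaboliteMatrix(
            intensities=pd.DataFrame(values[:, sl], index=birds, columns=feats),
            ion_mode=mode,
            hmdb_ids={f: f"HMDB_SIM_{f}" for f in feats},
            normalized=False,
        )
    return phenotypes, matrices["positive"], matrices["negative"]


def simulate_cohort(config: SimulationConfig):
    """Pedigree + phenotypes + metabolite panels in one call."""
    ped = simulate_pedigree(config)
    phenotypes, pos, neg = simulate_phenotypes(ped, config)
    return ped, phenotypes, pos, neg
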