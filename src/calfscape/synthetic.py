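"""Synthetic inputs: exact-samplable maxent communities, mock calf
studies, and non-Gaussian structural-equation data.

Three generators cover the three analysis stages:

* :func:`generate_community` draws states from an extended pairwise
  maximum-entropy model with known parameters (exact enumeration for
  all-binary systems, Gibbs otherwise) — the ground truth for parameter
  recovery.
* :func:`generate_study` builds a mock longitudinal study with the calf
  trial's design: 12 animals in two balanced groups (CON = treated with
  chlortetracycline, EXP = antibiotic-free), sampled at days 3/30/60,
  with genus-level relative abundances, 8 fecal chemical concentrations
  and serum physiology.  The "dysbiosis" profile plants a
  methanogen-like genus that the treatment promotes, a butyrate-producing
  genus that it suppresses, and correspondingly lower fecal butyrate.
* :func:`generate_sem` draws from a linear non-Gaussian acyclic SEM for
  testing causal discovery.

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maxent import MaxEntParams, exact_distribution, gibbs_sample
from .preprocess import ComponentMatrix, DAY_TO_STAGE, EnvironmentMatrix

__all__ = [
    "GroundTruthModel",
    "MockStudy",
    "SEMData",
    "generate_community",
    "generate_study",
    "generate_sem",
    "random_ground_truth",
    "METHANOGEN_GENUS",
    "BUTYRATE_PRODUCER_GENUS",
    "BUTYRATE_CHEMICAL",
]

METHANOGEN_GENUS = "Methanobrevibacter"
BUTYRATE_PRODUCER_GENUS = "Dorea"
BUTYRATE_CHEMICAL = "butyrate"

_EXACT_N_MAX = 20


@dataclass
class GroundTruthModel:
    """A maxent model with known parameters, for recovery experiments."""

    params: MaxEntParams
    component_kinds: list[str]
    environments: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.component_kinds) != self.params.n_components:
            raise ValueError("component_kinds length mismatch")
        for ea, es in self.environments:
            if ea not in (0.0, 1.0, 0, 1):
                raise ValueError("eps_a must be 0 or 1")
            if not 0.0 <= es <= 1.0:
                raise ValueError("eps_s must lie in [0, 1]")

    @property
    def n_components(self) -> int:
        return self.params.n_components

    @property
    def all_binary(self) -> bool:
        return all(k == "binary" for k in self.component_kinds)


def random_ground_truth(n_components: int, seed: int,
                        scale: float = 1.0,
                        null_g_a: bool = False,
                        environments: Optional[Sequence[tuple[float, float]]]
                        = None) -> GroundTruthModel:
    """All-binary ground truth with parameters drawn U(-scale, scale).

    The default environment grid is the study design: treatment in {0, 1}
    crossed with stages {0, 0.53, 1}.
    """
    rng = np.random.default_rng(seed)
    h = rng.uniform(-scale, scale, n_components)
    J = np.zeros((n_components, n_components))
    iu = np.triu_indices(n_components, k=1)
    J[iu] = rng.uniform(-scale, scale, iu[0].size)
    J = J + J.T
    g_a = (np.zeros(n_components) if null_g_a
           else rng.uniform(-scale, scale, n_components))
    g_s = rng.uniform(-scale, scale, n_components)
    envs = (list(environments) if environments is not None else
            [(a, s) for a in (0.0, 1.0) for s in sorted(DAY_TO_STAGE.values())])
    return GroundTruthModel(MaxEntParams(h, J, g_a, g_s),
                            ["binary"] * n_components, envs)


def generate_community(model: GroundTruthModel, n_samples_per_env: int,
                       seed: int, method: str = "auto"
                       ) -> tuple[ComponentMatrix, EnvironmentMatrix]:
    """Draw ``n_samples_per_env`` states from P(sigma | eps) per environment.

    ``method="exact"`` (all-binary only, N <= 20) draws iid states from the
    enumerated distribution; ``"gibbs"`` uses a thinned Gibbs chain per
    environment; ``"auto"`` picks exact when it applies.
    """
    n = model.n_components
    if method == "auto":
        method = "exact" if model.all_binary and n <= _EXACT_N_MAX else "gibbs"
    if method == "exact" and not model.all_binary:
        raise ValueError(
            "exact sampling requires all-binary components; use gibbs")
    rng = np.random.default_rng(seed)
    blocks, env_rows = [], []
    for ea, es in model.environments:
        if method == "exact":
            states, probs = exact_distribution(model.params, (ea, es))
            idx = rng.choice(probs.size, size=n_samples_per_env, p=probs)
            blocks.append(states[idx])
        else:
            thin = 5
            samples = gibbs_sample(
                model.params, (ea, es),
                n_sweeps=100 + thin * n_samples_per_env, seed=rng,
                component_kinds=model.component_kinds,
                burn_in=100, thin=thin)
            blocks.append(samples[:n_samples_per_env])
        env_rows.extend([(ea, es)] * n_samples_per_env)
    states = np.concatenate(blocks)
    sample_ids = [f"s{i:05d}" for i in range(states.shape[0])]
    names = (model.params.component_names
             or [f"c{i:02d}" for i in range(n)])
    values = pd.DataFrame(states, index=sample_ids, columns=names)
    comp = ComponentMatrix(values, list(model.component_kinds),
                           n_m=sum(k == "binary"
                                   for k in model.component_kinds),
                           n_c=sum(k != "binary"
                                   for k in model.component_kinds))
    env = EnvironmentMatrix(pd.DataFrame(env_rows, index=sample_ids,
                                         columns=["eps_a", "eps_s"]))
    return comp, env


# ---------------------------------------------------------------------------
# Mock calf study


@dataclass
class MockStudy:
    """A mock two-group longitudinal calf study.

    One sample per animal per day; abundance rows are relative and sum to
    one; chemical and physiological values are nonnegative concentrations.
    """

    metadata: pd.DataFrame    # animal_id, group, day; index = sample ids
    abundance: pd.DataFrame   # samples x taxa (QIIME-style taxonomy columns)
    chemicals: pd.DataFrame   # samples x 8 analytes
    physiology: pd.DataFrame  # samples x serum analytes
    effect_profile: str = "dysbiosis"
    seed: Optional[int] = None

    methanogen_genus: str = METHANOGEN_GENUS
    butyrate_producer_genus: str = BUTYRATE_PRODUCER_GENUS
    butyrate_chemical: str = BUTYRATE_CHEMICAL


def _taxonomy(phylum: str, family: str, genus: str,
              kingdom: str = "Bacteria") -> str:
    return (f"k__{kingdom};p__{phylum};c__;o__;f__{family};g__{genus}")


# (phylum, family, genus, baseline log-intensity, stage slope, treatment
# slope).  Baselines and slopes are on the natural-log intensity scale;
# relative abundances come from normalising exp(log-intensity) across
# genera, which reproduces the heavy-tailed, sparse look of genus tables.
# The treatment slope acts multiplicatively with growth stage, so day-3
# samples (stage 0) are unaffected — treatment effects build up over time.
_CORE_GENERA = [
    ("Bacteroidetes", "Bacteroidaceae", "Bacteroides", 4.2, 0.8, 0.0),
    ("Bacteroidetes", "Prevotellaceae", "Prevotella", 3.8, 1.5, 0.0),
    ("Firmicutes", "Ruminococcaceae", "Faecalibacterium", 3.6, 0.2, 0.0),
    ("Firmicutes", "Lachnospiraceae", "Blautia", 3.4, -0.3, 0.0),
]

_MID_GENERA = [
    # the two planted responders
    ("Euryarchaeota", "Methanobacteriaceae", METHANOGEN_GENUS,
     -2.5, 0.5, 5.0),
    ("Firmicutes", "Lachnospiraceae", BUTYRATE_PRODUCER_GENUS,
     -0.5, 2.0, -5.0),
    # mild treatment responders (|slope| ~ 1) in both directions
    ("Euryarchaeota", "Methanobacteriaceae", "Methanosphaera",
     -2.0, 0.3, 1.4),
    ("Firmicutes", "Lachnospiraceae", "Roseburia", -0.8, 1.2, -1.2),
    ("Firmicutes", "Lachnospiraceae", "Coprococcus", -0.6, 0.8, -1.0),
    ("Firmicutes", "Lachnospiraceae", "Butyrivibrio", -1.0, 1.0, -1.2),
    ("Firmicutes", "Lactobacillaceae", "Lactobacillus", 0.8, -1.8, -1.2),
    ("Proteobacteria", "Enterobacteriaceae", "Escherichia", 1.2, -2.2, 1.0),
    ("Proteobacteria", "Succinivibrionaceae", "Succinivibrio",
     -1.5, 1.4, -1.0),
    ("Firmicutes", "Clostridiaceae", "Clostridium", 0.2, -0.8, 1.0),
    ("Actinobacteria", "Bifidobacteriaceae", "Bifidobacterium",
     0.6, -1.6, -1.0),
    ("Firmicutes", "Erysipelotrichaceae", "Turicibacter", -1.2, 0.4, 1.2),
    # stage-driven or neutral filler taxa
    ("Firmicutes", "Ruminococcaceae", "Ruminococcus", -0.4, 1.2, 0.0),
    ("Firmicutes", "Ruminococcaceae", "Oscillospira", -0.9, 1.4, 0.0),
    ("Firmicutes", "Veillonellaceae", "Megasphaera", -1.1, 0.9, 0.0),
    ("Firmicutes", "Veillonellaceae", "Dialister", -1.3, 1.1, 0.0),
    ("Firmicutes", "Veillonellaceae", "Selenomonas", -1.6, 1.0, 0.0),
    ("Firmicutes", "Veillonellaceae", "Anaerovibrio", -1.4, 0.7, 0.0),
    ("Firmicutes", "Veillonellaceae", "Phascolarctobacterium",
     -0.7, 0.6, 0.0),
    ("Firmicutes", "Veillonellaceae", "Veillonella", -0.3, -1.2, 0.0),
    ("Firmicutes", "Erysipelotrichaceae", "Sarcina", -0.8, -0.9, 0.0),
    ("Firmicutes", "Streptococcaceae", "Streptococcus", 0.4, -1.5, 0.0),
    ("Firmicutes", "Enterococcaceae", "Enterococcus", -1.0, -1.1, 0.0),
    ("Bacteroidetes", "Porphyromonadaceae", "Parabacteroides",
     -0.5, 0.9, 0.0),
    ("Bacteroidetes", "Rikenellaceae", "Alistipes", -0.9, 1.2, 0.0),
    ("Bacteroidetes", "Porphyromonadaceae", "Odoribacter", -1.5, 0.8, 0.0),
    ("Bacteroidetes", "Prevotellaceae", "Paraprevotella", -1.7, 1.1, 0.0),
    ("Verrucomicrobia", "Verrucomicrobiaceae", "Akkermansia",
     -1.2, 0.5, 0.0),
    ("Actinobacteria", "Coriobacteriaceae", "Collinsella", -1.0, -0.5, 0.0),
    ("Actinobacteria", "Coriobacteriaceae", "Olsenella", -1.6, 0.3, 0.0),
    ("Actinobacteria", "Coriobacteriaceae", "Slackia", -1.9, 0.4, 0.0),
    ("Fibrobacteres", "Fibrobacteraceae", "Fibrobacter", -1.8, 1.3, 0.0),
    ("Spirochaetes", "Spirochaetaceae", "Treponema", -1.5, 1.2, 0.0),
    ("Proteobacteria", "Alcaligenaceae", "Sutterella", -1.3, 0.6, 0.0),
    ("Proteobacteria", "Desulfovibrionaceae", "Desulfovibrio",
     -1.7, 0.7, 0.0),
    ("Proteobacteria", "Campylobacteraceae", "Campylobacter",
     -1.4, -0.8, 0.0),
    ("Firmicutes", "Eubacteriaceae", "Eubacterium", -0.6, 0.5, 0.0),
    ("Firmicutes", "Christensenellaceae", "Christensenella",
     -1.8, 0.9, 0.0),
    ("Bacteroidetes", "S24-7", "Muribaculum", -1.2, 0.7, 0.0),
]

_RARE_GENERA = [
    ("Firmicutes", "Peptococcaceae", "Peptococcus", -7.0, 0.0, 0.0),
    ("Proteobacteria", "Moraxellaceae", "Acinetobacter", -7.5, 0.0, 0.0),
    ("Actinobacteria", "Micrococcaceae", "Rothia", -7.2, 0.0, 0.0),
    ("Firmicutes", "Planococcaceae", "Solibacillus", -7.8, 0.0, 0.0),
]

# chemical model: (name, intercept, stage slope, treatment-x-stage
# multiplier, lognormal sigma); concentrations in mmol/kg-feces-like units
_CHEMICALS = [
    ("lactate", 15.0, -10.0, 0.0, 0.40),
    ("acetate", 10.0, 40.0, 0.0, 0.20),
    ("propionate", 3.0, 25.0, -0.15, 0.30),
    (BUTYRATE_CHEMICAL, 2.0, 18.0, -0.50, 0.25),
    ("valerate", 0.5, 3.0, 0.0, 0.30),
    ("isovalerate", 0.5, 2.0, 0.0, 0.30),
    ("phosphate", 8.0, 2.0, 0.0, 0.15),
    ("succinate", 1.0, 2.0, 0.0, 0.50),
]

# serum analytes: (name, intercept, stage slope, treatment-x-stage
# multiplier, lognormal sigma)
_PHYSIOLOGY = [
    ("glucose", 110.0, -40.0, 0.0, 0.07),
    ("total_cholesterol", 80.0, 40.0, 0.0, 0.15),
    ("NEFA", 0.30, -0.10, 0.0, 0.20),
    ("BHBA", 0.05, 0.25, 0.0, 0.30),
    ("urea_nitrogen", 12.0, 4.0, 0.0, 0.20),
    ("calcium", 10.0, 0.0, 0.0, 0.05),
    ("IGF1", 60.0, 60.0, 0.15, 0.25),
    ("IgA", 0.50, 0.50, -0.40, 0.30),
]

_ANIMAL_SD = 0.3    # per-animal random effect on log intensity
_GENUS_NOISE_SD = 1.0


def generate_study(n_animals: int = 12, seed: int = 0,
                   effect_profile: str = "dysbiosis") -> MockStudy:
    """Mock calf study: balanced CON/EXP groups, days 3/30/60.

    ``effect_profile="dysbiosis"`` plants the treatment responses
    (methanogen up, butyrate producer and butyrate down under CTC, IGF-1
    up, IgA down); ``"null"`` removes every treatment effect while keeping
    the growth-stage dynamics.
    """
    if n_animals < 4:
        raise ValueError("design too small: need at least 4 animals")
    if n_animals % 2:
        raise ValueError("n_animals must be even for balanced groups")
    if effect_profile not in ("dysbiosis", "null"):
        raise ValueError(f"unknown effect_profile {effect_profile!r}")
    null = effect_profile == "null"
    rng = np.random.default_rng(seed)

    genera = _CORE_GENERA + _MID_GENERA + _RARE_GENERA
    tax_names = [_taxonomy(p, f, g, kingdom="Archaea"
                           if p == "Euryarchaeota" else "Bacteria")
                 for p, f, g, *_ in genera]
    mu = np.array([row[3] for row in genera])
    beta_s = np.array([row[4] for row in genera])
    beta_a = np.array([0.0 if null else row[5] for row in genera])

    days = sorted(DAY_TO_STAGE)
    animals = [f"A{i + 1:02d}" for i in range(n_animals)]
    groups = {a: ("CON" if i < n_animals // 2 else "EXP")
              for i, a in enumerate(animals)}
    animal_effect = {a: rng.normal(0.0, _ANIMAL_SD) for a in animals}

    meta_rows, ab_rows, chem_rows, phys_rows, sample_ids = [], [], [], [], []
    for a in animals:
        treated = 1.0 if groups[a] == "CON" else 0.0
        for day in days:
            s = DAY_TO_STAGE[day]
            sid = f"{a}_d{day:02d}"
            sample_ids.append(sid)
            meta_rows.append((a, groups[a], day))
            z = (mu + beta_s * s + beta_a * treated * s
                 + animal_effect[a]
                 + rng.normal(0.0, _GENUS_NOISE_SD, len(genera)))
            intensity = np.exp(z)
            ab_rows.append(intensity / intensity.sum())
            chem_rows.append([
                max((b0 + b1 * s) * (1.0 + (0.0 if null else ba) * treated * s)
                    * rng.lognormal(0.0, sg), 0.0)
                for (_, b0, b1, ba, sg) in _CHEMICALS])
            phys_rows.append([
                max((b0 + b1 * s) * (1.0 + (0.0 if null else ba) * treated * s)
                    * rng.lognormal(0.0, sg), 0.0)
                for (_, b0, b1, ba, sg) in _PHYSIOLOGY])

    metadata = pd.DataFrame(meta_rows, index=sample_ids,
                            columns=["animal_id", "group", "day"])
    abundance = pd.DataFrame(ab_rows, index=sample_ids, columns=tax_names)
    chemicals = pd.DataFrame(chem_rows, index=sample_ids,
                             columns=[c[0] for c in _CHEMICALS])
    physiology = pd.DataFrame(phys_rows, index=sample_ids,
                              columns=[p[0] for p in _PHYSIOLOGY])
    return MockStudy(metadata, abundance, chemicals, physiology,
                     effect_profile=effect_profile, seed=seed)


# ---------------------------------------------------------------------------
# Linear non-Gaussian SEM data


@dataclass
class SEMData:
    """Samples from x = B x + e with a recorded column shuffle.

    ``data`` columns are in shuffled order; column j of ``data`` is true
    variable ``permutation[j]``.  ``b_matrix`` stays in the true variable
    order (strictly lower triangular).
    """

    data: pd.DataFrame
    b_matrix: np.ndarray
    permutation: np.ndarray
    noise: list[tuple[str, float]]


def _draw_noise(kind: str, scale: float, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise with standard deviation ``scale``."""
    if kind == "uniform":
        half = scale * np.sqrt(3.0)
        return rng.uniform(-half, half, n)
    if kind == "laplace":
        return rng.laplace(0.0, scale / np.sqrt(2.0), n)
    if kind == "gaussian":
        return rng.normal(0.0, scale, n)
    raise ValueError(f"unknown noise kind {kind!r}")


def generate_sem(b_matrix: np.ndarray,
                 noise: Sequence[tuple[str, float]], n: int, seed: int,
                 shuffle: bool = True,
                 allow_gaussian: bool = False) -> SEMData:
    """Draw ``n`` samples from the SEM x = B x + e in true causal order.

    ``b_matrix`` must be strictly lower triangular (acyclic by
    construction); ``noise`` is a (kind, sd) pair per variable with kind
    in {"uniform", "laplace", "gaussian"}.  Gaussian noise destroys the
    identifiability of the causal direction; requesting it without
    ``allow_gaussian`` records a warning.
    """
    B = np.asarray(b_matrix, dtype=float)
    p = B.shape[0]
    if B.shape != (p, p):
        raise ValueError("b_matrix must be square")
    if np.any(np.triu(B) != 0):
        raise ValueError("b_matrix must be strictly lower triangular "
                         "(acyclic in the true order)")
    if len(noise) != p:
        raise ValueError("need one noise spec per variable")
    gaussian = [i for i, (kind, _) in enumerate(noise) if kind == "gaussian"]
    if gaussian and not allow_gaussian:
        warnings.warn(
            f"gaussian noise for variables {gaussian}: causal order is "
            "not identifiable", stacklevel=2)
    rng = np.random.default_rng(seed)
    e = np.column_stack([_draw_noise(kind, scale, n, rng)
                         for kind, scale in noise])
    x = np.zeros((n, p))
    for i in range(p):
        x[:, i] = x[:, :i] @ B[i, :i] + e[:, i]
    perm = rng.permutation(p) if shuffle else np.arange(p)
    data = pd.DataFrame(x[:, perm],
                        columns=[f"v{j}" for j in perm])
    return SEMData(data=data, b_matrix=B, permutation=perm,
                   noise=list(noise))
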