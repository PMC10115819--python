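"""From abundance/chemical/metadata tables to model-ready (sigma, eps).

Genus-level relative abundances are binarised at a detection threshold
(default 0.001, strict), taxa are kept only if their presence count over
all samples lies strictly between 2 and 35, chemical concentrations are
min-max scaled to [0, 1], and the two are stacked (taxa first) into a
ComponentMatrix.  Metadata (group CON/EXP, day 3/30/60) becomes the
EnvironmentMatrix: CON (treated) -> eps_a = 1, EXP -> 0; days map to
growth stages {3: 0, 30: 0.53, 60: 1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentMatrix",
    "EnvironmentMatrix",
    "DAY_TO_STAGE",
    "GROUP_TO_EPS_A",
    "binarize_abundance",
    "filter_prevalence",
    "scale_chemicals",
    "encode_environment",
    "assemble_components",
    "correlation_matrix",
    "genus_from_taxonomy",
    "collapse_to_genus",
    "preprocess_study",
]

DAY_TO_STAGE = {3: 0.0, 30: 0.53, 60: 1.0}
GROUP_TO_EPS_A = {"CON": 1.0, "EXP": 0.0}


@dataclass
class ComponentMatrix:
    """Per-sample state vectors: binary taxa followed by 0-1 chemicals."""

    values: pd.DataFrame                 # samples x N, taxa first
    component_kinds: list[str]           # "binary" | "continuous" per column
    n_m: int                             # number of taxon components
    n_c: int                             # number of chemical components

    def __post_init__(self) -> None:
        n = self.values.shape[1]
        if len(self.component_kinds) != n:
            raise ValueError("component_kinds length mismatch")
        if self.n_m + self.n_c != n:
            raise ValueError("n_m + n_c must equal the column count")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("component values must lie in [0, 1]")
        for j, kind in enumerate(self.component_kinds):
            if kind == "binary" and not np.isin(arr[:, j], (0.0, 1.0)).all():
                raise ValueError(
                    f"binary component {self.values.columns[j]!r} has "
                    "non-0/1 values")

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    @property
    def component_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def values_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class EnvironmentMatrix:
    """Per-sample (eps_a, eps_s): treatment indicator and scaled stage."""

    values: pd.DataFrame  # columns eps_a, eps_s, index = sample ids

    def __post_init__(self) -> None:
        missing = {"eps_a", "eps_s"} - set(self.values.columns)
        if missing:
            raise ValueError(f"environment table missing columns {missing}")

    @property
    def values_array(self) -> np.ndarray:
        return self.values[["eps_a", "eps_s"]].to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index.astype(str))


# ---------------------------------------------------------------------------


def genus_from_taxonomy(name: str) -> Optional[str]:
    """Genus label from a QIIME-classic taxonomy string.

    ``"k__Bacteria;...;g__Prevotella"`` -> ``"Prevotella"``; returns the
    input unchanged when it carries no rank prefixes; None when the genus
    field is empty/unassigned.
    """
    if ";" not in name and not name.strip().startswith(("k__", "g__")):
        return name.strip()
    for part in reversed(name.split(";")):
        part = part.strip()
        if part.startswith("g__"):
            genus = part[3:].strip()
            return genus or None
    return None


def collapse_to_genus(abundance: pd.DataFrame) -> pd.DataFrame:
    """Sum abundance columns sharing a genus; drop unassigned genera."""
    groups: dict[str, list[str]] = {}
    for col in abundance.columns:
        genus = genus_from_taxonomy(str(col))
        if genus is None:
            continue
        groups.setdefault(genus, []).append(col)
    out = {genus: abundance[cols].sum(axis=1)
           for genus, cols in groups.items()}
    return pd.DataFrame(out, index=abundance.index)


def binarize_abundance(abundance: pd.DataFrame,
                       threshold: float = 0.001) -> pd.DataFrame:
    """Presence/absence at a strict detection threshold.

    A taxon is called present when its relative abundance exceeds
    ``threshold`` strictly, so a value exactly at the threshold reads as
    absent (a detection limit).
    """
    arr = abundance.to_numpy(dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("negative relative abundances")
    return (abundance > threshold).astype(float)


def filter_prevalence(binary: pd.DataFrame, min_exclusive: int = 2,
                      max_exclusive: int = 35) -> list:
    """Taxa whose presence count lies strictly inside the window.

    With the defaults a taxon must appear in more than 2 but fewer than 35
    samples; column order is preserved.
    """
    counts = binary.sum(axis=0)
    kept = [c for c in binary.columns
            if min_exclusive < counts[c] < max_exclusive]
    if not kept:
        raise ValueError(
            "prevalence filter removed every taxon; presence counts: "
            f"{counts.to_dict()}")
    return kept


def scale_chemicals(chemicals: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte min-max scaling onto [0, 1].

    A constant analyte maps to all zeros (with a warning) rather than NaN
    so the model stays runnable.
    """
    arr = chemicals.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("chemical table contains non-finite values")
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        names = [c for c, flag in zip(chemicals.columns, constant) if flag]
        warnings.warn(f"constant analytes scaled to 0: {names}",
                      stacklevel=2)
    span = np.where(constant, 1.0, span)
    scaled = (arr - lo) / span
    scaled[:, constant] = 0.0
    return pd.DataFrame(scaled, index=chemicals.index,
                        columns=chemicals.columns)


def encode_environment(metadata: pd.DataFrame) -> EnvironmentMatrix:
    """Metadata (group, day) -> (eps_a, eps_s).

    CON (the antibiotic-treated group) encodes as eps_a = 1, EXP as 0;
    days 3/30/60 map to stages 0/0.53/1 with no interpolation.
    """
    bad_groups = set(metadata["group"]) - set(GROUP_TO_EPS_A)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    bad_days = set(int(d) for d in metadata["day"]) - set(DAY_TO_STAGE)
    if bad_days:
        raise ValueError(f"unknown sampling days: {sorted(bad_days)}")
    values = pd.DataFrame({
        "eps_a": [GROUP_TO_EPS_A[g] for g in metadata["group"]],
        "eps_s": [DAY_TO_STAGE[int(d)] for d in metadata["day"]],
    }, index=metadata.index)
    return EnvironmentMatrix(values)


def assemble_components(binary_taxa: pd.DataFrame,
                        scaled_chemicals: Optional[pd.DataFrame] = None
                        ) -> ComponentMatrix:
    """Stack binary taxa then scaled chemicals into one state matrix."""
    if scaled_chemicals is None or scaled_chemicals.shape[1] == 0:
        values = binary_taxa.copy()
        kinds = ["binary"] * binary_taxa.shape[1]
        return ComponentMatrix(values, kinds, binary_taxa.shape[1], 0)
    if list(binary_taxa.index) != list(scaled_chemicals.index):
        raise ValueError("sample IDs of taxa and chemicals are misaligned")
    values = pd.concat([binary_taxa, scaled_chemicals], axis=1)
    kinds = (["binary"] * binary_taxa.shape[1]
             + ["continuous"] * scaled_chemicals.shape[1])
    return ComponentMatrix(values, kinds, binary_taxa.shape[1],
                           scaled_chemicals.shape[1])


def correlation_matrix(acids: pd.DataFrame, genera: pd.DataFrame,
                       metadata: pd.DataFrame,
                       days: Sequence[int] = (30, 60)
                       ) -> dict[str, pd.DataFrame]:
    """Per-group Pearson r between each analyte and each taxon.

    Computed within CON and EXP separately, by default on the day-30/60
    samples only (the early-life day-3 community is still milk-driven).
    Zero-variance columns yield NaN, deliberately distinct from r = 0.
    """
    out: dict[str, pd.DataFrame] = {}
    day_mask = metadata["day"].astype(int).isin(days)
    for group in sorted(set(metadata["group"])):
        mask = (metadata["group"] == group) & day_mask
        idx = metadata.index[mask]
        if len(idx) < 3:
            raise ValueError(f"fewer than 3 samples in group {group!r}")
        a = acids.loc[idx].to_numpy(dtype=float)
        g = genera.loc[idx].to_numpy(dtype=float)
        a_c = a - a.mean(axis=0)
        g_c = g - g.mean(axis=0)
        a_sd = a_c.std(axis=0)
        g_sd = g_c.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (a_c.T @ g_c / len(idx)) / np.outer(a_sd, g_sd)
        r[~np.isfinite(r)] = np.nan
        out[group] = pd.DataFrame(r, index=acids.columns,
                                  columns=genera.columns)
    return out


def preprocess_study(abundance: pd.DataFrame, chemicals: pd.DataFrame,
                     metadata: pd.DataFrame, threshold: float = 0.001,
                     min_exclusive: int = 2, max_exclusive: int = 35
                     ) -> tuple[ComponentMatrix, EnvironmentMatrix]:
    """Full pipeline: collapse, binarise, filter, scale, encode, assemble."""
    genus_table = collapse_to_genus(abundance)
    binary = binarize_abundance(genus_table, threshold=threshold)
    kept = filter_prevalence(binary, min_exclusive, max_exclusive)
    scaled = scale_chemicals(chemicals.loc[binary.index])
    components = assemble_components(binary[kept], scaled)
    env = encode_environment(metadata.loc[binary.index])
    return components, env
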