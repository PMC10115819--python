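"""Plain-text readers and writers for study tables and fitted parameters.

Everything round-trips through TSV so results stay diffable and
version-controllable; an optional XLSX bundle mirrors the layout of a
single-workbook supplementary data file.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .maxent import FitResult, MaxEntParams
from .synthetic import MockStudy

__all__ = [
    "write_study_tsv",
    "read_abundance_tsv",
    "read_metadata_tsv",
    "read_chemicals_tsv",
    "write_params_tsv",
    "read_params_tsv",
    "write_study_xlsx",
]


def write_study_tsv(study: MockStudy, out_dir) -> dict[str, Path]:
    """Write abundance/metadata/chemicals/physiology TSVs; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in (("abundance", study.abundance),
                        ("metadata", study.metadata),
                        ("chemicals", study.chemicals),
                        ("physiology", study.physiology)):
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index_label="sample_id")
        paths[name] = path
    return paths


def write_study_xlsx(study: MockStudy, path) -> None:
    """Single-workbook export (one sheet per table), DataS1-style."""
    with pd.ExcelWriter(path) as writer:  # needs openpyxl
        study.metadata.to_excel(writer, sheet_name="metadata")
        study.abundance.to_excel(writer, sheet_name="abundance")
        study.chemicals.to_excel(writer, sheet_name="chemicals")
        study.physiology.to_excel(writer, sheet_name="physiology")


def read_abundance_tsv(path) -> pd.DataFrame:
    """Samples x taxa table; accepts QIIME-classic taxonomy headers."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_chemicals_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_params_tsv(fit: FitResult, out_dir) -> dict[str, Path]:
    """Serialise (h, J, g) + metadata; J follows the i<j once convention."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = fit.params
    n = params.n_components
    names = params.component_names or [f"c{i:02d}" for i in range(n)]
    paths = {}
    hg = pd.DataFrame({"component": names, "h": params.h,
                       "g_a": params.g_a, "g_s": params.g_s})
    if fit.p_values is not None:
        hg["p_h"] = fit.p_values.h
        hg["p_g_a"] = fit.p_values.g_a
        hg["p_g_s"] = fit.p_values.g_s
    paths["h_g"] = out / "h_g.tsv"
    hg.to_csv(paths["h_g"], sep="\t", index=False)
    jdf = pd.DataFrame(params.J, index=names, columns=names)
    paths["J"] = out / "J.tsv"
    jdf.to_csv(paths["J"], sep="\t", index_label="component")
    if fit.p_values is not None:
        pj = pd.DataFrame(fit.p_values.J, index=names, columns=names)
        paths["p_J"] = out / "p_J.tsv"
        pj.to_csv(paths["p_J"], sep="\t", index_label="component")
    meta = {
        "pair_convention": "each unordered pair counted once (i < j)",
        "seed": fit.seed,
        "n_reps": fit.n_reps,
        "settings": (vars(fit.settings) if fit.settings else None),
    }
    paths["meta"] = out / "fit_meta.json"
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return paths


def read_params_tsv(in_dir) -> MaxEntParams:
    """Load parameters written by :func:`write_params_tsv`."""
    in_dir = Path(in_dir)
    hg = pd.read_csv(in_dir / "h_g.tsv", sep="\t")
    jdf = pd.read_csv(in_dir / "J.tsv", sep="\t", index_col=0)
    return MaxEntParams(hg["h"].to_numpy(), jdf.to_numpy(),
                        hg["g_a"].to_numpy(), hg["g_s"].to_numpy(),
                        list(hg["component"].astype(str)))
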