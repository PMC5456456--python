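"""Readers and writers for the plain-text interchange formats.

Sub-study summary statistics travel as whitespace/tab-delimited tables (one
file per sub-study, or a single wide file), matching the distribution style of
consortium downloads: required columns SNP and Z, optional FRQ, N, NCASE and
NCONTROL.  Binned replication moments go to TSV with a JSON metadata sidecar;
fitted parameters and run configuration go to JSON.  Every artifact carries
provenance (package version, seed, settings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_model import MixtureParams
from .fitting import FitResult
from .resampling import BinnedMoments, SubstudyPanel

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_substudy_tables",
    "read_wide_table",
    "write_panel",
    "read_panel",
    "write_binned_moments",
    "read_binned_moments",
    "write_fit_result",
    "read_fit_result",
    "read_ld_pairs",
]

DEFAULT_COLUMNS = {"snp": "SNP", "z": "Z", "frq": "FRQ", "n": "N",
                   "ncase": "NCASE", "ncontrol": "NCONTROL"}


@dataclasses.dataclass
class RunConfig:
    """Resolved settings of a pipeline run; round-trips losslessly via JSON."""

    inputs: list = dataclasses.field(default_factory=list)
    columns: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    c: float = 10.0
    m_bins: int = 201
    train_fractions: list = dataclasses.field(default_factory=lambda: [0.5])
    n_iterations: int = 100
    partition_mode: str = "random"
    seed: int = 0
    fdr_alpha: float = 0.05
    p_threshold: float = 5e-8
    c_alpha: float = 1.6448536269514722
    out_dir: str = "."

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls(**json.loads(s))

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


def _provenance(**extra) -> dict:
    return {"package": "gwasmix", "version": __version__, **extra}


def _effective_n(df: pd.DataFrame, cols: dict) -> float | None:
    if cols["ncase"] in df.columns and cols["ncontrol"] in df.columns:
        ncase = float(np.median(df[cols["ncase"]]))
        nctrl = float(np.median(df[cols["ncontrol"]]))
        return 4.0 / (1.0 / ncase + 1.0 / nctrl)
    if cols["n"] in df.columns:
        return float(np.median(df[cols["n"]]))
    return None


def read_substudy_tables(paths, column_map: dict | None = None,
                         n_k=None) -> SubstudyPanel:
    """Aligned panel from per-sub-study summary-statistic files.

    Effective sample sizes come from (in order of precedence) the ``n_k``
    argument, per-file NCASE/NCONTROL columns (case-control balanced
    4/(1/ncase + 1/nctrl)), or a per-file N column.  SNPs missing from any
    sub-study are dropped (complete-case; the count is logged) and duplicate
    SNP identifiers are an error.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files given")
    frames, sizes = [], []
    for p in paths:
        df = pd.read_csv(p, sep=r"\s+")
        for required in (cols["snp"], cols["z"]):
            if required not in df.columns:
                raise ValueError(f"{p}: cannot resolve required column {required!r}")
        if df[cols["snp"]].duplicated().any():
            raise ValueError(f"{p}: duplicate SNP identifiers")
        if df[cols["z"]].isna().all():
            raise ValueError(f"{p}: study has no usable z-scores")
        sizes.append(_effective_n(df, cols))
        frames.append(df.set_index(cols["snp"]))
    if n_k is not None:
        sizes = list(np.asarray(n_k, dtype=float))
    if any(s is None for s in sizes):
        raise ValueError("effective sample sizes unavailable: pass n_k or provide N columns")
    n_before = max(len(f) for f in frames)
    z_cols = pd.concat([f[cols["z"]].rename(i) for i, f in enumerate(frames)],
                       axis=1, join="outer")
    complete = z_cols.dropna()
    dropped = len(z_cols) - len(complete)
    if dropped:
        logger.info("dropped %d of %d SNPs missing in at least one sub-study",
                    dropped, len(z_cols))
    if complete.empty:
        raise ValueError("no SNP present in every sub-study")
    freq = None
    if cols["frq"] in frames[0].columns:
        freq = frames[0][cols["frq"]].reindex(complete.index).to_numpy()
        if np.isnan(freq).any():
            freq = None
    del n_before
    return SubstudyPanel(snp_ids=complete.index.to_numpy(),
                         z=complete.to_numpy(), n_k=np.asarray(sizes, float),
                         allele_freq=freq)


def read_wide_table(path, snp_col: str = "SNP", z_cols=None, n_k=None,
                    frq_col: str = "FRQ") -> SubstudyPanel:
    """Panel from one wide file with a z-score column per sub-study."""
    df = pd.read_csv(path, sep=r"\s+")
    if z_cols is None:
        z_cols = [c for c in df.columns if c.upper().startswith("Z")]
    if not z_cols:
        raise ValueError(f"{path}: no z-score columns found")
    if df[snp_col].duplicated().any():
        raise ValueError(f"{path}: duplicate SNP identifiers")
    sub = df[[snp_col, *z_cols]].dropna()
    dropped = len(df) - len(sub)
    if dropped:
        logger.info("dropped %d of %d SNPs with missing cells", dropped, len(df))
    if n_k is None:
        raise ValueError("n_k is required for wide-format input")
    freq = None
    if frq_col in df.columns:
        freq = df.set_index(snp_col)[frq_col].reindex(sub[snp_col]).to_numpy()
    return SubstudyPanel(snp_ids=sub[snp_col].to_numpy(),
                         z=sub[z_cols].to_numpy(),
                         n_k=np.asarray(n_k, float), allele_freq=freq)


def write_panel(panel: SubstudyPanel, prefix) -> None:
    """Wide TSV (SNP, FRQ, Z1..ZK) plus JSON metadata with sample sizes."""
    prefix = Path(prefix)
    cols = {"SNP": panel.snp_ids}
    if panel.allele_freq is not None:
        cols["FRQ"] = panel.allele_freq
    for k in range(panel.n_studies):
        cols[f"Z{k + 1}"] = panel.z[:, k]
    pd.DataFrame(cols).to_csv(prefix.parent / (prefix.name + ".tsv"), sep="\t", index=False)
    meta = _provenance(n_k=list(map(float, panel.n_k)),
                       n_snps=int(panel.n_snps), n_studies=int(panel.n_studies))
    (prefix.parent / (prefix.name + ".json")).write_text(json.dumps(meta, indent=1))


def read_panel(prefix) -> SubstudyPanel:
    prefix = Path(prefix)
    meta = json.loads((prefix.parent / (prefix.name + ".json")).read_text())
    return read_wide_table(prefix.parent / (prefix.name + ".tsv"), n_k=meta["n_k"])


def write_binned_moments(bm: BinnedMoments, prefix) -> None:
    """TSV of per-bin moments plus a JSON sidecar with grid and scheme info."""
    prefix = Path(prefix)
    pd.DataFrame({
        "bin_mid": bm.bin_mid, "count": bm.count,
        "mean_rep": bm.mean_rep, "meansq_rep": bm.meansq_rep,
    }).to_csv(prefix.parent / (prefix.name + ".tsv"), sep="\t", index=False, na_rep="NA")
    core = dict(
        rho=bm.rho, n_train=bm.n_train, n_rep=bm.n_rep,
        train_fraction=bm.train_fraction, n_iterations=bm.n_iterations,
        bin_lo=float(bm.bin_edges[0]), bin_hi=float(bm.bin_edges[-1]),
        m_bins=int(len(bm.bin_edges) - 1))
    extra = {k: v for k, v in bm.meta.items() if k not in core}
    meta = _provenance(**core, **extra)
    (prefix.parent / (prefix.name + ".json")).write_text(json.dumps(meta, indent=1))


def read_binned_moments(prefix) -> BinnedMoments:
    prefix = Path(prefix)
    meta = json.loads((prefix.parent / (prefix.name + ".json")).read_text())
    df = pd.read_csv(prefix.parent / (prefix.name + ".tsv"), sep="\t", na_values="NA")
    edges = np.linspace(meta["bin_lo"], meta["bin_hi"], meta["m_bins"] + 1)
    keep = {k: v for k, v in meta.items()
            if k not in {"package", "version", "rho", "n_train", "n_rep",
                         "train_fraction", "n_iterations", "bin_lo", "bin_hi", "m_bins"}}
    return BinnedMoments(bin_edges=edges, count=df["count"].to_numpy(float),
                         mean_rep=df["mean_rep"].to_numpy(float),
                         meansq_rep=df["meansq_rep"].to_numpy(float),
                         rho=meta["rho"], n_train=meta["n_train"], n_rep=meta["n_rep"],
                         train_fraction=meta.get("train_fraction"),
                         n_iterations=meta.get("n_iterations", 1), meta=keep)


def write_fit_result(result: FitResult, path) -> None:
    payload = _provenance(**result.to_dict())
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_result(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    return FitResult(theta_hat=MixtureParams.from_dict(d["theta_hat"]),
                     objective=d["objective"], converged=d["converged"],
                     n_restarts=d["n_restarts"], degenerate=d.get("degenerate", False),
                     rho_set=tuple(d.get("rho_set", ())),
                     provenance=d.get("provenance", {}))


def read_ld_pairs(path, snp_to_index: dict | None = None):
    """Pairwise LD table (SNP_A, SNP_B, R2) as an (i, j, r2) pair list."""
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    if snp_to_index is None:
        names = pd.unique(pd.concat([df["SNP_A"], df["SNP_B"]]))
        snp_to_index = {name: i for i, name in enumerate(names)}
    return [(snp_to_index[a], snp_to_index[b], float(r))
            for a, b, r in zip(df["SNP_A"], df["SNP_B"], df["R2"])
            if a in snp_to_index and b in snp_to_index], snp_to_index
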