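"""Run configuration, deterministic seeding, and readers/writers for every
external format the pipeline touches.

Formats are deliberately text-only: tall TSV for perturbation signatures,
labelled TSV matrices for basal expression and drug sensitivity, CSV for
survival cohorts and dose-response tables, GMT for gene set collections, and
16-bit grayscale TIFF for micrographs.  Signatures use a tall TSV rather than
a binary GCTX dialect; a GCTX converter is a documented extension point, not
a dependency.

Absent tensor cells are stored as *missing* (NaN in memory, no row on disk),
never as zero, so that downstream recurrence denominators count only the
cell lines actually measured.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

logger = logging.getLogger("recscreen")

SIGNATURE_COLUMNS = ("compound", "gene", "cell_line", "timepoint", "z")
SURVIVAL_COLUMNS = ("patient_id", "time", "event")

#: LINCS cell-line panel used throughout as the default axis of recurrence.
DEFAULT_CELL_LINES: tuple[str, ...] = (
    "A357", "A549", "HA1E", "HCC515", "HEPG2",
    "HT29", "MCF7", "NPC", "PC3", "VCAP",
)
#: Perturbation profile timepoints (d6 / d24 in the screening convention).
DEFAULT_TIMEPOINTS: tuple[str, ...] = ("6h", "24h")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Configuration and seeding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of the pipeline in one place.

    Defaults encode the screening rules of the analysis: compounds must show
    recurrent downregulation at FDR <= 1e-3 and rank in the top 30 most
    negative REC scores per target gene and timepoint, and basal-expression /
    sensitivity correlation must reach p <= 0.05.  GSEA runs 1000
    permutations on sets of 10-500 genes with a q < 0.25 significance rule.
    """

    seed: int = 0
    rec_z_threshold: float = 2.0
    rec_fdr_max: float = 1e-3
    corr_p_max: float = 0.05
    rec_top_k: int = 30
    rec_permutations: int = 999
    rec_p_method: str = "exact"        # "exact" | "permutation"
    rec_null: str = "gene"             # "gene" | "compound" label resampling
    corr_method: str = "pearson"       # "pearson" | "spearman"
    gsea_permutations: int = 1000
    gsea_set_min: int = 10
    gsea_set_max: int = 500
    gsea_q_max: float = 0.25
    gsea_weight: float = 1.0
    scan_min_group: int = 8
    mito_blur_sigma_px: float = 1.0
    mito_min_object_px: int = 3

    def __post_init__(self) -> None:
        for name in ("rec_z_threshold", "rec_top_k", "rec_permutations",
                     "gsea_permutations", "gsea_set_min", "gsea_set_max",
                     "scan_min_group", "mito_min_object_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("rec_fdr_max", "corr_p_max", "gsea_q_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.gsea_set_min > self.gsea_set_max:
            raise ValueError("gsea_set_min must be <= gsea_set_max")
        if self.mito_blur_sigma_px < 0:
            raise ValueError("mito_blur_sigma_px must be nonnegative")
        if self.rec_p_method not in ("exact", "permutation"):
            raise ValueError("rec_p_method must be 'exact' or 'permutation'")
        if self.rec_null not in ("gene", "compound"):
            raise ValueError("rec_null must be 'gene' or 'compound'")
        if self.corr_method not in ("pearson", "spearman"):
            raise ValueError("corr_method must be 'pearson' or 'spearman'")

    def hash(self) -> str:
        """Stable 12-hex-digit digest of the full configuration."""
        items = sorted(dataclasses.asdict(self).items())
        blob = ";".join(f"{k}={v!r}" for k, v in items).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def substream(seed: int, *names: object) -> np.random.Generator:
    """Named, independent random substream derived from the master seed.

    Every source of randomness in the pipeline draws from a substream so that
    two runs with equal config and inputs are bit-identical, and adding a new
    consumer of randomness never perturbs existing ones.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Signature tensor
# ---------------------------------------------------------------------------

@dataclass
class SignatureTensor:
    """Perturbation differential-expression z values over
    (compound, gene, cell_line, timepoint); NaN marks an unmeasured cell.
    """

    z: xr.DataArray

    def __post_init__(self) -> None:
        if tuple(self.z.dims) != ("compound", "gene", "cell_line", "timepoint"):
            self.z = self.z.transpose("compound", "gene", "cell_line", "timepoint")

    @property
    def compounds(self) -> list[str]:
        return [str(c) for c in self.z.coords["compound"].values]

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.z.coords["gene"].values]

    @property
    def cell_lines(self) -> list[str]:
        return [str(c) for c in self.z.coords["cell_line"].values]

    @property
    def timepoints(self) -> list[str]:
        return [str(t) for t in self.z.coords["timepoint"].values]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(self.z.shape)  # type: ignore[return-value]

    def slice(self, compound: str, gene: str, timepoint: str) -> np.ndarray:
        """z values across cell lines for one (compound, gene, timepoint)."""
        try:
            return np.asarray(
                self.z.sel(compound=compound, gene=gene, timepoint=timepoint).values,
                dtype=float,
            )
        except KeyError as exc:
            raise KeyError(
                f"({compound!r}, {gene!r}, {timepoint!r}) not present in tensor"
            ) from exc

    def to_frame(self) -> pd.DataFrame:
        """Tall (compound, gene, cell_line, timepoint, z) frame, absent cells dropped."""
        df = self.z.to_dataframe(name="z").reset_index()
        df = df.dropna(subset=["z"])
        return df.sort_values(list(SIGNATURE_COLUMNS[:4])).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureTensor":
        idx = df.set_index(list(SIGNATURE_COLUMNS[:4]))["z"]
        da = idx.to_xarray()
        # normalize label order on every axis
        da = da.sortby(["compound", "gene", "cell_line", "timepoint"])
        return cls(z=da)

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        compounds: Sequence[str],
        genes: Sequence[str],
        cell_lines: Sequence[str],
        timepoints: Sequence[str],
    ) -> "SignatureTensor":
        da = xr.DataArray(
            np.asarray(values, dtype=float),
            dims=("compound", "gene", "cell_line", "timepoint"),
            coords={
                "compound": list(compounds),
                "gene": list(genes),
                "cell_line": list(cell_lines),
                "timepoint": list(timepoints),
            },
        )
        return cls(z=da.sortby(["compound", "gene", "cell_line", "timepoint"]))


def read_signature_tensor(path: str | Path) -> SignatureTensor:
    """Read a tall-TSV perturbation signature file.

    Expects header columns compound, gene, cell_line, timepoint, z.  Missing
    (compound, gene, cell_line) cells are marked absent, never zero.
    Duplicate keys and non-numeric z values are hard errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SIGNATURE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise DataError(f"{path}: no records")
    z = pd.to_numeric(df["z"], errors="coerce")
    bad = z.isna() & df["z"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0])
        raise DataError(
            f"{path}: non-numeric z value {df['z'].iloc[row]!r} at data row {row + 1}"
        )
    df = df.assign(z=z)
    keys = list(SIGNATURE_COLUMNS[:4])
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        first = df.loc[dup, keys].iloc[0]
        raise DataError(
            f"{path}: duplicate signature key "
            f"({first['compound']}, {first['gene']}, "
            f"{first['cell_line']}, {first['timepoint']})"
        )
    return SignatureTensor.from_frame(df)


def write_signature_tensor(
    tensor: SignatureTensor, path: str | Path, config: RunConfig | None = None
) -> None:
    write_table(tensor.to_frame(), path, config, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; members are deduplicated and
    order-insensitive."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        if name in self.sets:
            raise DataError(f"duplicate gene set name {name!r}")
        deduped = tuple(dict.fromkeys(members))
        if not deduped:
            raise DataError(f"gene set {name!r} has no members")
        self.sets[name] = (description, deduped)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a standard GMT file (name TAB description TAB member...)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            try:
                coll.add(name, desc, members)
            except DataError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from exc
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc, members = collection.sets[name]
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

def read_survival_csv(path: str | Path) -> pd.DataFrame:
    """Read a patient survival table.

    Columns: patient_id, time, event (1 = death observed, 0 = censored),
    plus one column per gene.  Records with a missing expression value are
    excluded and the exclusion is logged.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "patient_id"].iloc[0]
        raise DataError(f"{path}: non-positive survival time for patient {bad!r}")
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "patient_id"].iloc[0]
        raise DataError(f"{path}: event must be 0 or 1 (patient {bad!r})")
    gene_cols = [c for c in df.columns if c not in SURVIVAL_COLUMNS]
    incomplete = df[gene_cols].isna().any(axis=1)
    if incomplete.any():
        dropped = df.loc[incomplete, "patient_id"].tolist()
        logger.warning(
            "excluded %d record(s) with missing expression: %s",
            len(dropped), ", ".join(map(str, dropped)),
        )
        df = df.loc[~incomplete]
    df = df.reset_index(drop=True)
    df["event"] = df["event"].astype(int)
    return df


def write_survival_csv(
    cohort: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    write_table(cohort, path, config, sep=",")


# ---------------------------------------------------------------------------
# Labelled matrices, dose-response tables, generic TSV
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | Path, index_name: str | None = None) -> pd.DataFrame:
    """Read a labelled numeric matrix (first column = row labels)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if index_name is not None:
        df.index.name = index_name
    return df.sort_index().sort_index(axis=1)


def write_matrix_tsv(
    matrix: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    write_table(matrix.sort_index().sort_index(axis=1), path, config,
                sep="\t", index=True)


def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    """Read a viability-vs-dose table with columns dose, viability, replicate."""
    df = pd.read_csv(path, comment="#")
    for col in ("dose", "viability"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if (df["dose"] < 0).any():
        raise DataError(f"{path}: negative dose")
    if not np.isfinite(df["viability"]).all():
        raise DataError(f"{path}: non-finite viability")
    return df.sort_values(["dose", "replicate"]).reset_index(drop=True)


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    sep: str = "\t",
    index: bool = False,
) -> None:
    """Write a table with a reproducibility header comment.

    The header line carries the config hash and seed so every artifact is
    traceable to the run that produced it.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# recscreen config_hash={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, sep=sep, index=index, float_format="%.10g", lineterminator="\n")


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")
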