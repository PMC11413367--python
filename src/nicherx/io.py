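"""Data model and on-disk formats.

The pipeline's central container is :class:`ObsMatrix`, a genes x observations
count (or normalized) matrix with per-observation metadata.  Matrices are
stored on disk as MatrixMarket coordinate files with genes as rows; an
``%%orientation=`` comment line makes the orientation explicit so matrices
written by other tools (observations as rows) can still be ingested.  Gene
sets travel as GMT, drug dictionaries as TSV, everything tabular as CSV.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

LAYERS = ("raw_counts", "normalized", "log_transformed", "clr")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator.

    Every stochastic stage derives its stream from the run seed and its own
    name, so adding or reordering stages never perturbs the others.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class ObsMatrix:
    """Genes x observations expression matrix with observation metadata.

    Parameters
    ----------
    values
        Sparse or dense numeric matrix, genes as rows.
    gene_ids, obs_ids
        Unique identifier lists matching the matrix dimensions.
    obs_meta
        DataFrame indexed by ``obs_id`` with at least ``sample_id`` and
        ``tissue`` columns; extra label columns are carried along untouched.
    layer
        One of ``raw_counts``, ``normalized``, ``log_transformed``, ``clr``.
    meta
        Free-form provenance (e.g. ``log_base``, ``target_sum``).
    """

    values: sp.spmatrix | np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    obs_meta: pd.DataFrame
    layer: str = "raw_counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
        else:
            self.values = np.asarray(self.values)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n_genes, n_obs = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.obs_ids) != n_obs:
            raise ValidationError(
                f"{len(self.obs_ids)} obs ids for {n_obs} matrix columns"
            )
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.obs_ids, "obs_ids")
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if not self.obs_meta.index.equals(pd.Index(self.obs_ids)):
            if set(self.obs_meta.index) != set(self.obs_ids):
                raise ValidationError("obs_meta does not cover every obs_id exactly once")
            self.obs_meta = self.obs_meta.loc[self.obs_ids]
        for col in ("sample_id", "tissue"):
            if col not in self.obs_meta.columns:
                raise ValidationError(f"obs_meta missing required column {col!r}")
        if self.layer == "raw_counts":
            data = self.values.data if sp.issparse(self.values) else self.values
            if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
                raise ValidationError("raw_counts layer must hold non-negative integers")

    # -- conveniences --------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return values as a dense float array (genes x obs)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of the requested symbols (present ones, input order)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset(self, genes: np.ndarray | None = None, obs: np.ndarray | None = None) -> "ObsMatrix":
        """Index by integer positions along either axis; metadata follows."""
        values = self.values
        gene_ids = self.gene_ids
        obs_ids = self.obs_ids
        if genes is not None:
            genes = np.asarray(genes)
            values = values[genes, :]
            gene_ids = [gene_ids[i] for i in genes]
        if obs is not None:
            obs = np.asarray(obs)
            values = values[:, obs]
            obs_ids = [obs_ids[i] for i in obs]
        return ObsMatrix(
            values=values,
            gene_ids=list(gene_ids),
            obs_ids=list(obs_ids),
            obs_meta=self.obs_meta.loc[obs_ids].copy(),
            layer=self.layer,
            meta=dict(self.meta),
        )


@dataclass
class SpotCoordinates:
    """Planar spot positions, one sample per spot."""

    table: pd.DataFrame  # columns: sample_id, obs_id, x, y

    def __post_init__(self) -> None:
        required = {"sample_id", "obs_id", "x", "y"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"coordinates missing columns {sorted(missing)}")
        _check_unique(self.table["obs_id"].tolist(), "coordinate obs_id")
        xy = self.table[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError("coordinates must be finite")

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.table[self.table["sample_id"] == sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.table["sample_id"]))


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"gene set {self.name!r}")


@dataclass
class DrugRecord:
    drug_id: str
    name: str
    atc_code: str
    approved: bool
    viable: bool
    targets: list[str]

    def __post_init__(self) -> None:
        if not self.atc_code:
            raise ValidationError(f"drug {self.drug_id!r} has empty ATC code")
        if not self.targets:
            logger.warning("drug %s has no targets; it will be excluded downstream", self.drug_id)


@dataclass
class RunManifest:
    """Provenance record written by every CLI stage."""

    seed: int
    config: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = ""

    def add_stage(self, stage: str, params: dict, paths: dict) -> None:
        self.outputs[stage] = {"params": params, "paths": {k: str(v) for k, v in paths.items()}}

    def write(self, path: str | Path) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        payload = {
            "seed": self.seed,
            "config": self.config,
            "stages": self.outputs,
            "version": self.version,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            raise ValidationError(f"duplicate identifier {item!r} in {what}")
        seen.add(item)


# ---------------------------------------------------------------------------
# matrix IO
# ---------------------------------------------------------------------------

_ORIENT_TAG = "%%orientation="


def read_matrix(
    mtx_path: str | Path,
    genes_tsv: str | Path,
    obs_tsv: str | Path,
    meta_csv: str | Path | None = None,
    layer: str = "raw_counts",
    meta: dict | None = None,
) -> ObsMatrix:
    """Read a MatrixMarket matrix plus identifier files into an ObsMatrix.

    The matrix is reoriented to genes x observations regardless of the on-disk
    orientation, declared by an ``%%orientation=obs_x_genes`` comment line
    (genes-as-rows assumed when absent).
    """
    mtx_path, genes_tsv, obs_tsv = Path(mtx_path), Path(genes_tsv), Path(obs_tsv)
    values = scipy.io.mmread(str(mtx_path))
    orientation = _read_orientation(mtx_path)
    if orientation == "obs_x_genes":
        values = values.T if sp.issparse(values) else np.asarray(values).T
    gene_ids = _read_id_column(genes_tsv)
    obs_ids = _read_id_column(obs_tsv)
    if values.shape[0] != len(gene_ids):
        raise FormatError(
            f"{mtx_path.name}: {values.shape[0]} gene rows but "
            f"{genes_tsv.name} lists {len(gene_ids)} identifiers"
        )
    if values.shape[1] != len(obs_ids):
        raise FormatError(
            f"{mtx_path.name}: {values.shape[1]} observation columns but "
            f"{obs_tsv.name} lists {len(obs_ids)} identifiers"
        )
    if meta_csv is not None:
        obs_meta = pd.read_csv(meta_csv, index_col=0, dtype={0: str})
        obs_meta.index = obs_meta.index.astype(str)
    else:
        obs_meta = pd.DataFrame(
            {"sample_id": "S0", "tissue": "spatial"}, index=pd.Index(obs_ids, name="obs_id")
        )
    if layer == "raw_counts" and sp.issparse(values):
        values = values.astype(np.int64)
    return ObsMatrix(
        values=values if sp.issparse(values) else np.asarray(values),
        gene_ids=gene_ids,
        obs_ids=obs_ids,
        obs_meta=obs_meta,
        layer=layer,
        meta=meta or {},
    )


def write_matrix(matrix: ObsMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx / genes.tsv / barcodes.tsv / obs_meta.csv / layer.json.

    Integer layers round-trip bit-exactly; float layers are written with six
    significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "obs_meta": out_dir / "obs_meta.csv",
        "layer": out_dir / "layer.json",
    }
    values = matrix.values if sp.issparse(matrix.values) else sp.coo_matrix(matrix.values)
    integral = matrix.layer == "raw_counts"
    scipy.io.mmwrite(
        str(paths["matrix"]),
        values.astype(np.int64) if integral else values.astype(np.float64),
        comment="orientation=genes_x_obs",
        field="integer" if integral else "real",
        precision=None if integral else 7,
    )
    paths["genes"].write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    paths["barcodes"].write_text("".join(f"{o}\n" for o in matrix.obs_ids))
    matrix.obs_meta.rename_axis("obs_id").to_csv(paths["obs_meta"])
    paths["layer"].write_text(json.dumps({"layer": matrix.layer, "meta": matrix.meta}, default=str))
    return paths


def read_matrix_dir(directory: str | Path) -> ObsMatrix:
    """Read back a directory produced by :func:`write_matrix`."""
    directory = Path(directory)
    layer_info = {"layer": "raw_counts", "meta": {}}
    layer_file = directory / "layer.json"
    if layer_file.exists():
        layer_info = json.loads(layer_file.read_text())
    return read_matrix(
        directory / "matrix.mtx",
        directory / "genes.tsv",
        directory / "barcodes.tsv",
        directory / "obs_meta.csv",
        layer=layer_info["layer"],
        meta=layer_info.get("meta", {}),
    )


def _read_orientation(mtx_path: Path) -> str:
    with open(mtx_path) as fh:
        for line in fh:
            if not line.startswith("%"):
                break
            stripped = line.strip()
            # mmwrite prefixes user comments with "% "; accept both spellings
            for tag in (_ORIENT_TAG, "% orientation=", "%orientation="):
                if stripped.startswith(tag):
                    return stripped[len(tag):].strip()
    return "genes_x_obs"


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------


def read_coordinates(path: str | Path) -> SpotCoordinates:
    table = pd.read_csv(path, dtype={"sample_id": str, "obs_id": str})
    return SpotCoordinates(table=table)


def write_coordinates(coords: SpotCoordinates, path: str | Path) -> Path:
    path = Path(path)
    coords.table.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate symbols within a line are collapsed (first occurrence wins) with
    a logged count; the description field is discarded.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{Path(path).name}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "gene set %s: collapsed %d duplicate symbols", name, len(genes) - len(deduped)
                )
            sets.append(GeneSet(name=name, genes=deduped))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# drug dictionary
# ---------------------------------------------------------------------------

_DRUG_COLUMNS = ["drug_id", "name", "atc_code", "approved", "viable", "targets"]


def read_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read a TSV drug dictionary; targets are pipe-separated gene symbols."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DRUG_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing drug table columns {missing}")
    records = []
    for row in table.itertuples(index=False):
        targets = [t for t in str(row.targets).split("|") if t]
        records.append(
            DrugRecord(
                drug_id=row.drug_id,
                name=row.name,
                atc_code=row.atc_code,
                approved=_parse_bool(row.approved),
                viable=_parse_bool(row.viable),
                targets=targets,
            )
        )
    return records


def write_drug_table(drugs: Sequence[DrugRecord], path: str | Path) -> Path:
    path = Path(path)
    table = pd.DataFrame(
        {
            "drug_id": [d.drug_id for d in drugs],
            "name": [d.name for d in drugs],
            "atc_code": [d.atc_code for d in drugs],
            "approved": [str(d.approved).lower() for d in drugs],
            "viable": [str(d.viable).lower() for d in drugs],
            "targets": ["|".join(d.targets) for d in drugs],
        }
    )
    table.to_csv(path, sep="\t", index=False)
    return path


def _parse_bool(text: str) -> bool:
    text = str(text).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise FormatError(f"cannot parse boolean value {text!r}")
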