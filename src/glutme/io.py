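"""Readers and writers for the plain-text formats the pipeline exchanges.

Bulk expression travels as TSV (genes x samples), gene sets as GMT,
single-cell counts as MatrixMarket (genes x rows convention: genes as rows,
cells as columns, matching the usual droplet-pipeline layout) with gene and
cell label files, response cohorts and sample sheets as CSV, PET volumes as
NIfTI with spherical VOIs in a small YAML file (world mm coordinates).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml
from scipy import io as scio
from scipy import sparse

from .exceptions import ParameterError
from .pet import PetStudy, Sphere
from .synthetic import BulkCohort, ScCohort

# --- bulk expression ---------------------------------------------------------


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        raise ParameterError(f"duplicate gene ids in {path}")
    return expr


def write_bulk_cohort(cohort: BulkCohort, outdir) -> None:
    """Write expression TSV, sample sheet CSV and the signature GMT to a directory."""
    os.makedirs(outdir, exist_ok=True)
    write_expression_tsv(cohort.expression, os.path.join(outdir, "expression.tsv"))
    cohort.samples.to_csv(os.path.join(outdir, "samples.csv"), index_label="sample_id")
    cohort.signatures.to_gmt(os.path.join(outdir, "signatures.gmt"))


# --- response cohorts --------------------------------------------------------


def write_response_cohort(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


def read_response_cohort(path) -> pd.DataFrame:
    from .response import validate_response_cohort

    data = pd.read_csv(path)
    data["event"] = data["event"].astype(bool)
    return validate_response_cohort(data)


# --- single-cell -------------------------------------------------------------


def write_sc_cohort(cohort: ScCohort, outdir) -> None:
    """Write counts.mtx (genes x cells), genes.tsv and cells.tsv (with cell_type)."""
    os.makedirs(outdir, exist_ok=True)
    matrix = sparse.csr_matrix(cohort.counts.to_numpy().T)
    scio.mmwrite(os.path.join(outdir, "counts.mtx"), matrix)
    pd.Series(cohort.counts.columns, name="gene_id").to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False
    )
    cells = pd.DataFrame({"cell_id": cohort.counts.index, "cell_type": cohort.cell_types.to_numpy()})
    cells.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index=False)


def read_sc_counts(mtx_path, genes_path, cells_path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a genes x cells MatrixMarket file into a cells x genes DataFrame."""
    matrix = scio.mmread(mtx_path)
    genes = pd.read_csv(genes_path, sep="\t")["gene_id"]
    cells = pd.read_csv(cells_path, sep="\t")
    dense = np.asarray(matrix.todense() if sparse.issparse(matrix) else matrix)
    if dense.shape != (len(genes), len(cells)):
        raise ParameterError(
            f"matrix shape {dense.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    counts = pd.DataFrame(dense.T, index=cells["cell_id"], columns=genes)
    cell_types = None
    if "cell_type" in cells.columns:
        cell_types = pd.Series(cells["cell_type"].to_numpy(), index=cells["cell_id"], name="cell_type")
    return counts, cell_types


# --- PET ---------------------------------------------------------------------


def write_nifti(suv: np.ndarray, spacing, path) -> None:
    import nibabel as nib

    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(suv, dtype=np.float32), affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), spacing


def read_voi_yaml(path) -> dict[str, Sphere]:
    """Read tumor/liver spheres from YAML: ``{tumor: {center_mm: [x,y,z], radius_mm: r}, liver: ...}``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = {}
    for name in ("tumor", "liver"):
        if name not in cfg:
            raise ParameterError(f"VOI config is missing the {name!r} sphere")
        spec = cfg[name]
        out[name] = Sphere(center_mm=tuple(float(v) for v in spec["center_mm"]), radius_mm=float(spec["radius_mm"]))
    return out


def read_pet_study(volume_path, voi_path) -> PetStudy:
    suv, spacing = read_nifti(volume_path)
    vois = read_voi_yaml(voi_path)
    return PetStudy(suv=suv, spacing=spacing, tumor_voi=vois["tumor"], liver_voi=vois["liver"])
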