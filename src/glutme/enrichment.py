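"""Single-sample gene-set enrichment and the ImmuneScore summation.

The immune enrichment of a bulk tumor sample is summarised by scoring a small
collection of immune cell-type signatures (B cells, CD4+/CD8+ T cells,
dendritic cells, eosinophils, macrophages, monocytes, mast cells, neutrophils
and NK cells) with a rank-based single-sample running-sum statistic (ssGSEA)
and summing the ten per-type scores into a single ImmuneScore.  A glycolysis
signature scored the same way gives the sample's glycolysis enrichment score.

Scores are rank statistics: they are invariant under any strictly monotone
transform of the expression values of a sample, so it does not matter whether
the input matrix holds log-normalized values, TPMs or raw counts, as long as
within-sample ordering is meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateGeneSetError, EmptyGeneSetError, ParameterError

logger = logging.getLogger(__name__)

#: The ten immune cell types whose enrichment scores are summed into ImmuneScore.
IMMUNE_SUMMAND_TYPES: tuple[str, ...] = (
    "B_cells",
    "CD4_T_cells",
    "CD8_T_cells",
    "Dendritic_cells",
    "Eosinophils",
    "Macrophages",
    "Monocytes",
    "Mast_cells",
    "Neutrophils",
    "NK_cells",
)

GLYCOLYSIS_SIGNATURE = "Glycolysis"
IMMUNE_SCORE_COLUMN = "ImmuneScore"


@dataclass
class SignatureCollection:
    """Named gene sets with a flag marking the immune-summand signatures.

    Parameters
    ----------
    sets
        Mapping of signature name to its (non-empty) gene list.
    immune_summands
        Names of the signatures whose scores are summed into ImmuneScore.
    """

    sets: dict[str, list[str]]
    immune_summands: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ParameterError(f"signature {name!r} has an empty gene list")
        missing = [n for n in self.immune_summands if n not in self.sets]
        if missing:
            raise ParameterError(f"immune-summand signatures not in collection: {missing}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @classmethod
    def from_gmt(cls, path, immune_summands: tuple[str, ...] | None = None) -> "SignatureCollection":
        """Read a GMT file (name TAB description TAB gene...).

        A signature whose description field contains the token ``immune-summand``
        is flagged as part of the ImmuneScore sum; an explicit ``immune_summands``
        argument overrides the file's flags.
        """
        sets: dict[str, list[str]] = {}
        flagged: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParameterError(f"malformed GMT line: {line[:80]!r}")
                name, description, genes = parts[0], parts[1], [g for g in parts[2:] if g]
                sets[name] = genes
                if "immune-summand" in description:
                    flagged.append(name)
        if immune_summands is None:
            immune_summands = tuple(flagged)
        return cls(sets=sets, immune_summands=immune_summands)

    def to_gmt(self, path) -> None:
        """Write the collection as GMT, encoding the immune flag in the description."""
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = "immune-summand" if name in self.immune_summands else "na"
                fh.write("\t".join([name, desc, *genes]) + "\n")


def _ranked_order(values: pd.Series) -> pd.Series:
    """Sample values sorted by descending expression, ties broken by gene id."""
    # mergesort is stable: pre-sorting by gene id makes the tie-break deterministic
    return values.sort_index(kind="mergesort").sort_values(ascending=False, kind="mergesort")


def ssgsea_score(sample_expression: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample running-sum enrichment score of one gene set in one sample.

    Genes are ranked by descending expression (ties broken by gene id).  At
    each rank position the in-set running fraction, weighted by
    ``(rank from bottom)**alpha``, is compared with the out-of-set running
    fraction; the score is the sum of the differences over all positions.
    Positive scores mean the set concentrates at the top of the ranking.

    Parameters
    ----------
    sample_expression
        Expression of one sample indexed by gene id.
    gene_set
        Iterable of gene ids. Genes absent from the sample are ignored.
    alpha
        Rank-weighting exponent; 0 gives the unweighted Kolmogorov-Smirnov-like
        running sum, 0.25 is the conventional single-sample GSEA weight.

    Raises
    ------
    EmptyGeneSetError
        If no gene of the set is present in the sample.
    DegenerateGeneSetError
        If the set covers every gene (no out-of-set genes to compare against).
    """
    if alpha < 0:
        raise ParameterError("alpha must be nonnegative")
    members = set(gene_set) & set(sample_expression.index)
    if not members:
        raise EmptyGeneSetError("gene set has no overlap with the expression vector")
    if len(members) == len(sample_expression):
        raise DegenerateGeneSetError("gene set covers all genes; enrichment undefined")

    ranked = _ranked_order(sample_expression)
    in_set = ranked.index.isin(members)
    n = len(ranked)
    weights = (np.arange(n, 0, -1, dtype=float)) ** alpha  # rank counted from the bottom
    w_in = np.where(in_set, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_set) / float((~in_set).sum())
    return float(np.sum(p_in - p_out))


def score_cohort(
    expression: pd.DataFrame,
    signatures: SignatureCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Score every signature in every sample and derive the ImmuneScore.

    Parameters
    ----------
    expression
        Genes x samples matrix with unique gene ids as index.
    signatures
        The signature collection; signatures flagged as immune summands are
        summed per sample into the ``ImmuneScore`` column.
    alpha
        Rank-weighting exponent passed to :func:`ssgsea_score`.
    normalize
        If True, min-max normalize each signature's scores across the cohort
        after scoring (off by default; the raw running-sum statistic is kept).

    Returns
    -------
    pandas.DataFrame
        Samples x signatures score table with an extra ``ImmuneScore`` column.
    """
    if expression.index.has_duplicates:
        raise ParameterError("expression matrix has duplicate gene ids")
    gene_index = expression.index
    members: dict[str, np.ndarray] = {}
    for name in signatures:
        genes = signatures[name]
        present = gene_index.isin(genes)
        n_present = int(present.sum())
        if n_present == 0:
            raise EmptyGeneSetError(f"signature {name!r} has no genes in the expression matrix")
        if n_present == len(gene_index):
            raise DegenerateGeneSetError(f"signature {name!r} covers every gene in the matrix")
        dropped = len(set(genes)) - n_present
        if dropped:
            logger.info("signature %s: %d genes absent from the matrix were dropped", name, dropped)
        members[name] = present

    n = len(gene_index)
    weights = (np.arange(n, 0, -1, dtype=float)) ** alpha
    out = pd.DataFrame(index=expression.columns, columns=list(signatures), dtype=float)
    id_sorted = expression.sort_index(kind="mergesort")
    for sample in expression.columns:
        ranked_idx = id_sorted[sample].sort_values(ascending=False, kind="mergesort").index
        pos = gene_index.get_indexer(ranked_idx)
        for name, present in members.items():
            in_set = present[pos]
            w_in = np.where(in_set, weights, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~in_set) / float((~in_set).sum())
            out.loc[sample, name] = float(np.sum(p_in - p_out))
    if normalize:
        rng = out.max() - out.min()
        rng = rng.replace(0.0, 1.0)
        out = (out - out.min()) / rng
    immune_cols = list(signatures.immune_summands)
    out[IMMUNE_SCORE_COLUMN] = out[immune_cols].sum(axis=1) if immune_cols else 0.0
    return out
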