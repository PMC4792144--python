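"""Expression analytics: RPKM quantification, qPCR relative expression by
the 2^-ddCt method, Pearson correlation, and signed co-expression networks
over externally supplied candidate interaction edges.

RPKM for a gene with C mapped reads, exon-model length L (bp), in a library
of N mapped reads, is 10^9 * C / (N * L).  Relative qPCR expression uses
dCt = Ct_target - Ct_reference per sample, ddCt = dCt_condition -
dCt_calibrator, fold = 2^-ddCt (so the calibrator fold is identically 1).
Network edge signs follow the Pearson coefficient's zero crossing; edges
whose correlation cannot be computed (zero variance, or a gene missing from
the expression matrix) are reported as ``na`` with the cause.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples read counts plus gene lengths and library sizes."""

    counts: pd.DataFrame            # genes x samples
    gene_lengths: pd.Series         # bp, > 0
    library_sizes: pd.Series | None = None  # mapped reads per sample

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative read counts")
        lengths = self.gene_lengths.reindex(self.counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise FormatError("every gene needs a positive exon-model length")
        self.gene_lengths = lengths
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        sizes = self.library_sizes.reindex(self.counts.columns)
        if sizes.isna().any() or (sizes <= 0).any():
            raise FormatError("every sample needs a positive mapped-read total")
        self.library_sizes = sizes


def rpkm(count: float, exon_model_length_bp: float, mapped_total: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_model_length_bp <= 0 or mapped_total <= 0:
        raise FormatError("length and mapped total must be positive")
    return 1e9 * count / (mapped_total * exon_model_length_bp)


def rpkm_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-cell RPKM for a whole expression matrix."""
    counts = expr.counts.to_numpy(dtype=float)
    lengths = expr.gene_lengths.to_numpy(dtype=float)[:, None]
    totals = expr.library_sizes.to_numpy(dtype=float)[None, :]
    values = 1e9 * counts / (totals * lengths)
    return pd.DataFrame(values, index=expr.counts.index,
                        columns=expr.counts.columns)


def heatmap_export(abundance: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) transform used for heatmap-ready TSV export."""
    return np.log2(abundance + 1.0)


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt
# ---------------------------------------------------------------------------

def ddct_fold_change(ct_table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Per gene/condition fold changes by 2^-ddCt.

    ``ct_table`` needs columns gene, condition, ct_target, ct_reference;
    replicate rows of the same (gene, condition) are averaged on the dCt
    scale.  Every gene must have rows for the calibrator condition.
    """
    required = {"gene", "condition", "ct_target", "ct_reference"}
    missing = required - set(ct_table.columns)
    if missing:
        raise FormatError(f"ct table missing columns {sorted(missing)}")
    work = ct_table.copy()
    if not np.isfinite(work[["ct_target", "ct_reference"]].to_numpy()).all():
        raise FormatError("non-finite Ct values")
    work["dct"] = work["ct_target"] - work["ct_reference"]
    mean_dct = work.groupby(["gene", "condition"], sort=False)["dct"].mean()
    rows = []
    for gene in work["gene"].unique():
        gene_dct = mean_dct.loc[gene]
        if calibrator not in gene_dct.index:
            raise FormatError(
                f"gene {gene!r} has no rows for calibrator condition {calibrator!r}")
        base = gene_dct.loc[calibrator]
        for condition, dct in gene_dct.items():
            rows.append({
                "gene": gene, "condition": condition,
                "ddct": dct - base, "fold": 2.0 ** (base - dct),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation + network
# ---------------------------------------------------------------------------

def pcc(x, y) -> float | None:
    """Pearson correlation; None when not calculable (zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FormatError("pcc needs two equal-length vectors")
    if x.size < 3:
        raise FormatError("pcc needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class NetworkEdge:
    wrky_id: str
    partner_id: str
    pcc: float | None
    sign: str              # positive | negative | na
    na_cause: str = ""     # "zero_variance" or "missing" when sign == na
    provenance: str = ""


def coexpression_network(expr: pd.DataFrame,
                         candidate_edges: list[tuple],
                         min_abs_r: float = 0.0) -> list[NetworkEdge]:
    """Annotate candidate interaction edges with expression correlations.

    ``expr`` is an abundance matrix (genes x samples); candidates are
    (wrky_id, partner_id[, provenance]) tuples.  Candidates whose genes are
    absent from the matrix are emitted with sign ``na`` and a warning.
    An optional |r| filter turns weak correlations into sign ``na``.
    """
    edges = []
    for cand in candidate_edges:
        wrky, partner = cand[0], cand[1]
        provenance = cand[2] if len(cand) > 2 else ""
        if wrky not in expr.index or partner not in expr.index:
            warnings.warn(f"candidate edge {wrky}-{partner}: gene missing "
                          "from expression matrix")
            edges.append(NetworkEdge(wrky, partner, None, "na",
                                     na_cause="missing", provenance=provenance))
            continue
        r = pcc(expr.loc[wrky].to_numpy(), expr.loc[partner].to_numpy())
        if r is None:
            edges.append(NetworkEdge(wrky, partner, None, "na",
                                     na_cause="zero_variance",
                                     provenance=provenance))
        elif r > min_abs_r:
            edges.append(NetworkEdge(wrky, partner, r, "positive",
                                     provenance=provenance))
        elif r < -min_abs_r:
            edges.append(NetworkEdge(wrky, partner, r, "negative",
                                     provenance=provenance))
        else:
            edges.append(NetworkEdge(wrky, partner, r, "na",
                                     na_cause="below_threshold",
                                     provenance=provenance))
    return edges


def network_sign_counts(edges: list[NetworkEdge]) -> dict[str, int]:
    counts = {"positive": 0, "negative": 0, "na": 0,
              "na_zero_variance": 0, "na_missing": 0}
    for e in edges:
        counts[e.sign] += 1
        if e.sign == "na" and e.na_cause == "zero_variance":
            counts["na_zero_variance"] += 1
        if e.sign == "na" and e.na_cause == "missing":
            counts["na_missing"] += 1
    return counts
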