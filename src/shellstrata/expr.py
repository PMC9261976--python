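"""Expression utilities: TPM, median-centered heatmap matrices, 3' extension.

TPM is computed from counts and effective lengths (the estimation of those
counts is upstream's business); heatmap matrices are row median-centered
and max-abs scaled, matching a red-above-median / blue-below color scheme;
the GFF3 gene-model extension pushes 3' ends out by a fixed distance
(default 2 kb) to compensate for poorly annotated UTRs, clamped to contig
bounds and strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "compute_tpm",
    "tpm_matrix",
    "median_center",
    "extend_gene_models_3prime",
    "read_gff3",
    "write_gff3",
    "read_contig_lengths",
]


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------
def compute_tpm(counts, effective_lengths) -> np.ndarray:
    """Transcripts per million from counts and effective lengths.

    rate_i = count_i / length_i; TPM_i = 1e6 * rate_i / sum(rate).  An
    all-zero count vector yields an all-zero TPM vector (not NaN).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must align")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be > 0")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return rate / total * 1e6


def tpm_matrix(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Column-wise TPM for a gene x stage count table."""
    lengths = lengths.loc[counts.index]
    out = {
        col: compute_tpm(counts[col].to_numpy(), lengths.to_numpy())
        for col in counts.columns
    }
    return pd.DataFrame(out, index=counts.index)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row median-center and max-abs scale into [-1, 1].

    Values above the row median become positive (plotted red), below
    negative (blue); constant rows map to all zeros.
    """
    values = matrix.to_numpy(dtype=float)
    centered = values - np.median(values, axis=1, keepdims=True)
    scale = np.abs(centered).max(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return pd.DataFrame(centered / scale, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class GeneModel:
    """One GFF3 feature line (1-based inclusive coordinates)."""

    contig: str
    source: str
    feature_type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid coordinates {self.start}-{self.end} on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_gff3(path: str | Path) -> list[GeneModel]:
    models = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"GFF3 line does not have 9 columns: {line!r}")
        models.append(
            GeneModel(f[0], f[1], f[2], int(f[3]), int(f[4]), f[5], f[6], f[7], f[8])
        )
    return models


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        lines.append(
            "\t".join(
                [
                    m.contig, m.source, m.feature_type, str(m.start), str(m.end),
                    m.score, m.strand, m.phase, m.attributes,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV: contig name, length."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split("\t")[:2]
        out[name] = int(length)
    return out


def extend_gene_models_3prime(
    models: list[GeneModel],
    contig_lengths: dict[str, int],
    extension: int = 2000,
) -> list[GeneModel]:
    """Extend each model by ``extension`` bp in the 3' direction.

    Plus-strand models grow at ``end`` (clamped to the contig length),
    minus-strand models at ``start`` (clamped to 1).  All other fields are
    preserved; an unknown contig is a hard error naming the record.
    """
    out = []
    for m in models:
        if m.contig not in contig_lengths:
            raise KeyError(
                f"unknown contig {m.contig!r} for feature at "
                f"{m.start}-{m.end} ({m.attributes})"
            )
        clen = contig_lengths[m.contig]
        if m.end > clen:
            raise ValueError(f"feature end {m.end} exceeds contig length {clen}")
        if m.strand == "+":
            out.append(replace(m, end=min(m.end + extension, clen)))
        else:
            out.append(replace(m, start=max(m.start - extension, 1)))
    return out
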