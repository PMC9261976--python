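"""Signal-peptide and transmembrane-segment annotation.

Two sources feed one per-gene feature table: built-in heuristics — a
Kyte–Doolittle sliding-window scan for transmembrane segments and an
N-terminal charge+hydrophobic-core rule for signal peptides — and parsers
for the short tabular outputs of the dedicated predictors (SignalP 5.0
summaries, TMHMM 2.0 one-line format).  The heuristics are deliberately
simple stand-ins; the parsers are the fidelity path for real data.  A
``provenance`` column records which source produced each row.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KYTE_DOOLITTLE",
    "ProteinFeature",
    "hydropathy_tm_scan",
    "predict_signal_peptide",
    "annotate_proteome",
    "parse_predictor_outputs",
    "count_features",
]

# Kyte & Doolittle hydropathy index, the classical scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class ProteinFeature:
    gene_id: str
    has_signal_peptide: bool
    tm_segments: list[tuple[int, int]]
    max_window_hydropathy: float

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.tm_segments:
            if start <= prev_end or end < start:
                raise ValueError("tm_segments must be sorted and non-overlapping")
            prev_end = end


def _hydropathy(seq: str) -> np.ndarray:
    vals = np.zeros(len(seq))
    unknown = 0
    for i, ch in enumerate(seq.upper()):
        try:
            vals[i] = KYTE_DOOLITTLE[ch]
        except KeyError:
            unknown += 1
    if unknown:
        logger.warning("%d unknown residue(s) scored 0", unknown)
    return vals


def hydropathy_tm_scan(
    seq: str, window: int = 19, threshold: float = 1.6
) -> tuple[list[tuple[int, int]], float]:
    """Sliding-window Kyte–Doolittle scan for transmembrane-like segments.

    Windows whose mean hydropathy reaches ``threshold`` are merged into
    maximal segments (1-based inclusive coordinates).  For sequences
    shorter than the window no segment is reported and the maximum is
    taken over the single full-length window.
    """
    if not seq:
        raise ValueError("empty sequence")
    vals = _hydropathy(seq)
    if len(seq) < window:
        return [], float(vals.mean())
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    hot = np.flatnonzero(means >= threshold)
    segments: list[tuple[int, int]] = []
    for i in hot:
        start, end = i + 1, i + window  # 1-based inclusive
        if segments and start <= segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], end)
        else:
            segments.append((start, end))
    return segments, float(means.max())


def predict_signal_peptide(
    seq: str,
    n_region: int = 5,
    h_core_min: int = 6,
    search_len: int = 30,
    core_hydropathy: float = 1.6,
) -> bool:
    """Heuristic signal-peptide call from the canonical N/H-region anatomy.

    True iff the first ``n_region`` residues carry at least one positive
    charge (K/R) and, within the first ``search_len`` residues but starting
    after the initiator position, some run of ``h_core_min`` consecutive
    residues has mean hydropathy >= ``core_hydropathy``.
    """
    if not seq:
        raise ValueError("empty sequence")
    head = seq[:n_region].upper()
    if not any(ch in "KR" for ch in head):
        return False
    region = seq[:search_len]
    if len(region) < h_core_min + 1:
        return False
    vals = _hydropathy(region)
    means = np.convolve(vals, np.ones(h_core_min) / h_core_min, mode="valid")
    return bool((means[1:] >= core_hydropathy).any())


def annotate_proteome(
    sequences: dict[str, str], window: int = 19, threshold: float = 1.6
) -> pd.DataFrame:
    """Heuristic feature table (provenance ``heuristic``) for a gene->seq map."""
    rows = []
    for gid, seq in sequences.items():
        segs, maxh = hydropathy_tm_scan(seq, window, threshold)
        rows.append(
            {
                "gene_id": gid,
                "has_signal_peptide": predict_signal_peptide(seq),
                "tm_count": len(segs),
                "tm_segments": ";".join(f"{a}-{b}" for a, b in segs),
                "max_window_hydropathy": maxh,
                "provenance": "heuristic",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "has_signal_peptide", "tm_count",
            "tm_segments", "max_window_hydropathy", "provenance",
        ],
    )


# ---------------------------------------------------------------------------
# real predictor short formats
# ---------------------------------------------------------------------------
def _parse_signalp5(path: str | Path) -> pd.DataFrame:
    """SignalP 5.0 tabular summary: ID, Prediction, SP(Sec/SPI), OTHER, CS."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            logger.warning("skipping malformed SignalP line: %r", line)
            continue
        pred = fields[1].strip()
        try:
            sp_likelihood = float(fields[2])
        except ValueError:
            sp_likelihood = float("nan")
        rows.append(
            {
                "gene_id": fields[0].strip(),
                "has_signal_peptide": pred.startswith("SP") and sp_likelihood > 0.5,
                "sp_likelihood": sp_likelihood,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "has_signal_peptide", "sp_likelihood"])


_PREDHEL = re.compile(r"PredHel=(\d+)")


def _parse_tmhmm2(path: str | Path) -> pd.DataFrame:
    """TMHMM 2.0 short format: one line per protein with ``PredHel=N``."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        m = _PREDHEL.search(line)
        if m is None:
            logger.warning("skipping TMHMM line without PredHel: %r", line)
            continue
        rows.append(
            {"gene_id": line.split("\t")[0].strip(), "tm_count": int(m.group(1))}
        )
    return pd.DataFrame(rows, columns=["gene_id", "tm_count"])


def parse_predictor_outputs(
    signalp5_path: str | Path | None = None,
    tmhmm2_path: str | Path | None = None,
) -> pd.DataFrame:
    """Merge SignalP 5.0 and TMHMM 2.0 short outputs into a feature table.

    Genes present in only one file keep missing values in the other's
    columns (warned, not raised).  Provenance is ``parsed``.
    """
    if signalp5_path is None and tmhmm2_path is None:
        raise ValueError("at least one predictor output is required")
    sp = _parse_signalp5(signalp5_path) if signalp5_path else None
    tm = _parse_tmhmm2(tmhmm2_path) if tmhmm2_path else None
    if sp is not None and tm is not None:
        only = set(sp.gene_id) ^ set(tm.gene_id)
        if only:
            logger.warning("%d gene(s) present in only one predictor file", len(only))
        merged = sp.merge(tm, on="gene_id", how="outer")
    else:
        merged = sp if sp is not None else tm
    merged = merged.sort_values("gene_id").reset_index(drop=True)
    merged["provenance"] = "parsed"
    return merged


def count_features(
    features: pd.DataFrame, genes: list[str] | None = None
) -> tuple[int, int, int]:
    """(n with TM domains, n with signal peptides, n total) over a gene subset.

    Accepts either a boolean ``has_tm`` column or an integer ``tm_count``.
    """
    if genes is not None:
        missing = set(genes) - set(features["gene_id"])
        if missing:
            raise KeyError(f"genes not in feature table: {sorted(missing)}")
        features = features[features["gene_id"].isin(set(genes))]
    if "has_tm" in features.columns:
        n_tm = int(features["has_tm"].fillna(False).astype(bool).sum())
    else:
        n_tm = int((features["tm_count"].fillna(0) >= 1).sum())
    n_sp = int(features["has_signal_peptide"].fillna(False).astype(bool).sum())
    return n_tm, n_sp, len(features)
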