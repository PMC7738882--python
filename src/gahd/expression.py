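"""Differential expression by the log2-ratio / diverge-probability rule.

A gene is called differentially expressed when the depth-normalized
|log2-ratio| between the two libraries is at least 1 (2-fold) and the
"diverge probability" is at least 0.8. The diverge probability here is
defined through the Audic-Claverie model for digital expression counts:
given the count ``x`` in library A, the count in library B follows the
posterior-predictive negative binomial with ``n = x + 1`` and
``p = N_A / (N_A + N_B)``; the diverge probability is one minus twice the
smaller tail at the observed B count — 0 for perfectly concordant counts,
approaching 1 for strongly divergent ones. Both thresholds are inclusive
and exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountTable",
    "DEGRecord",
    "log2_ratio",
    "diverge_probability",
    "call_degs",
]


@dataclass
class CountTable:
    """Two-condition gene-level counts with library sizes."""

    gene_ids: list[str]
    counts_a: np.ndarray
    counts_b: np.ndarray
    library_size_a: float
    library_size_b: float

    def __post_init__(self) -> None:
        self.counts_a = np.asarray(self.counts_a)
        self.counts_b = np.asarray(self.counts_b)
        if not (len(self.gene_ids) == len(self.counts_a) == len(self.counts_b)):
            raise ValueError("gene_ids and count columns must have equal length")
        if self.library_size_a <= 0 or self.library_size_b <= 0:
            raise ValueError("library sizes must be > 0")
        if np.any(self.counts_a < 0) or np.any(self.counts_b < 0):
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        """Read a TSV with columns gene_id, count_a, count_b.

        Library sizes come from '#library_size_a=' / '#library_size_b='
        header lines when present, else from the column sums.
        """
        lib_a = lib_b = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#library_size_a="):
                    lib_a = float(line.strip().split("=", 1)[1])
                elif line.startswith("#library_size_b="):
                    lib_b = float(line.strip().split("=", 1)[1])
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["gene_id", "count_a", "count_b"])
        a = df["count_a"].to_numpy()
        b = df["count_b"].to_numpy()
        return cls(
            df["gene_id"].astype(str).tolist(),
            a,
            b,
            lib_a if lib_a is not None else float(a.sum()),
            lib_b if lib_b is not None else float(b.sum()),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#library_size_a={self.library_size_a:g}\n")
            fh.write(f"#library_size_b={self.library_size_b:g}\n")
            for g, a, b in zip(self.gene_ids, self.counts_a, self.counts_b):
                fh.write(f"{g}\t{int(a)}\t{int(b)}\n")


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2_ratio: float
    diverge_probability: float
    call: str  # up / down / unchanged


def log2_ratio(
    count_a: float,
    count_b: float,
    lib_a: float,
    lib_b: float,
    pseudocount: float = 1.0,
) -> float:
    """log2 of the depth-normalized B/A expression ratio (pseudocounted)."""
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be > 0")
    return float(
        np.log2(((count_b + pseudocount) / lib_b) / ((count_a + pseudocount) / lib_a))
    )


def diverge_probability(
    count_a: float,
    count_b: float,
    lib_a: float,
    lib_b: float,
) -> float:
    """Audic-Claverie divergence score in [0, 1].

    ``1 - 2 * min(P(X <= b), P(X >= b))`` where X is the posterior-predictive
    count in library B given ``count_a`` and the library-size ratio. No
    pseudocount: the model handles zeros natively.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be >= 0")
    a = int(round(count_a))
    b = int(round(count_b))
    p_success = lib_a / (lib_a + lib_b)
    lower = stats.nbinom.cdf(b, a + 1, p_success)
    upper = 1.0 - stats.nbinom.cdf(b - 1, a + 1, p_success)
    return float(max(0.0, 1.0 - 2.0 * min(lower, upper)))


def call_degs(
    table: CountTable,
    min_log2_ratio: float = 1.0,
    min_diverge_probability: float = 0.8,
    pseudocount: float = 1.0,
) -> tuple[list[DEGRecord], dict[str, int]]:
    """Per-gene DEG calls plus {n_up, n_down, n_unchanged} summary.

    Thresholds are inclusive: log2-ratio exactly at the threshold with
    diverge probability exactly at its threshold is called.
    """
    a = np.asarray(table.counts_a, dtype=float)
    b = np.asarray(table.counts_b, dtype=float)
    la, lb = table.library_size_a, table.library_size_b
    lr = np.log2(((b + pseudocount) / lb) / ((a + pseudocount) / la))

    ai = np.round(a).astype(np.int64)
    bi = np.round(b).astype(np.int64)
    p_success = la / (la + lb)
    lower = stats.nbinom.cdf(bi, ai + 1, p_success)
    upper = 1.0 - stats.nbinom.cdf(bi - 1, ai + 1, p_success)
    dp = np.maximum(0.0, 1.0 - 2.0 * np.minimum(lower, upper))

    records: list[DEGRecord] = []
    summary = {"n_up": 0, "n_down": 0, "n_unchanged": 0}
    for gid, r, d in zip(table.gene_ids, lr, dp):
        if r >= min_log2_ratio and d >= min_diverge_probability:
            call = "up"
            summary["n_up"] += 1
        elif r <= -min_log2_ratio and d >= min_diverge_probability:
            call = "down"
            summary["n_down"] += 1
        else:
            call = "unchanged"
            summary["n_unchanged"] += 1
        records.append(DEGRecord(gid, float(r), float(d), call))
    return records, summary


def write_deg_table(records: Sequence[DEGRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2_ratio\tdiverge_probability\tcall\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.log2_ratio:.6f}\t{r.diverge_probability:.6f}\t{r.call}\n"
            )
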