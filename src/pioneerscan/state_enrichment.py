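"""Chromatin-state overlap enrichment of motif classes.

Given a state segmentation that tiles the genome and bound / sampled /
unsampled motif sets, computes for each (state, class) pair the fold
enrichment of class bases in that state over the state's genome fraction:

    fold(s, c) = (bases of c in s / total bases of c) / (bases of s / G)

Enrichment is computed in bases (half-open overlap), not motif counts, so
it is insensitive to motif length heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import GenomeDescription, GenomeInterval, StateSegmentation

__all__ = ["OverlapEnrichment", "overlap_enrichment", "enrichment_report",
           "read_report"]


@dataclass
class OverlapEnrichment:
    fold: pd.DataFrame            # states × classes
    genome_fraction: pd.Series    # per state
    class_bases: pd.DataFrame     # states × classes, overlap bases
    class_totals: pd.Series       # per class, total bases


def overlap_enrichment(
    segmentation: StateSegmentation,
    classed_motifs: dict[str, list[GenomeInterval]],
    genome: GenomeDescription,
) -> OverlapEnrichment:
    """Base-resolution fold enrichment of each class in each state."""
    segmentation.validate_coverage(genome)
    states = list(range(1, segmentation.n_states + 1))
    classes = list(classed_motifs)

    # sorted segmentation arrays per chromosome for binary-search lookup
    seg_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    state_bases = {s: 0 for s in states}
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in segmentation.intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
        state_bases[int(iv.name)] += len(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda i: i.start)
        seg_by_chrom[chrom] = (
            np.array([i.start for i in ivs]),
            np.array([i.end for i in ivs]),
            np.array([int(i.name) for i in ivs]),
        )

    bases = pd.DataFrame(0, index=states, columns=classes, dtype=int)
    for cls, ivs in classed_motifs.items():
        for iv in ivs:
            iv.validate(genome)
            starts, ends, labels = seg_by_chrom[iv.chrom]
            i = int(np.searchsorted(starts, iv.start, side="right")) - 1
            pos = iv.start
            while pos < iv.end:
                ov = min(iv.end, ends[i]) - pos
                bases.loc[int(labels[i]), cls] += ov
                pos += ov
                i += 1

    g = genome.total_size
    genome_fraction = pd.Series(
        {s: state_bases[s] / g for s in states}, name="genome_fraction"
    )
    class_totals = bases.sum(axis=0)
    fold = pd.DataFrame(index=states, columns=classes, dtype=float)
    for cls in classes:
        total = class_totals[cls]
        for s in states:
            if total == 0:
                fold.loc[s, cls] = np.nan
            else:
                fold.loc[s, cls] = (bases.loc[s, cls] / total) / genome_fraction[s]
    return OverlapEnrichment(fold, genome_fraction, bases, class_totals)


def enrichment_report(
    e: OverlapEnrichment,
    state_labels: dict[int, str],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Long-format (state, class) table with fold and both marginals."""
    missing = [s for s in e.fold.index if s not in state_labels]
    if missing:
        raise ValueError(f"missing labels for states {missing}")
    rows = []
    for s in e.fold.index:
        for cls in e.fold.columns:
            rows.append(
                {
                    "state": s,
                    "state_label": state_labels[s],
                    "class": cls,
                    "fold_enrichment": e.fold.loc[s, cls],
                    "genome_fraction": e.genome_fraction[s],
                    "class_fraction": (
                        e.class_bases.loc[s, cls] / e.class_totals[cls]
                        if e.class_totals[cls]
                        else np.nan
                    ),
                }
            )
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
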