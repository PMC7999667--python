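"""Protein k-mer screening with a triple-repeat high-confidence rule.

Proteins are cut exhaustively into all contiguous substrings of lengths
``k = 2..9`` by a sliding window. A classifier is trained from scratch
``n_repeats`` times (three by default, each with its own seed) on the
full training dataset, and every k-mer is scored in each repeat. A k-mer
is a *candidate* ACE-inhibitory peptide only when its predicted positive
probability exceeds 0.99 in every repeat — repetition filters out
borderline scores that depend on training stochasticity. Two control
bins are kept for downstream comparison: k-mers whose probabilities all
round to 0.00 (confident negatives) and those that all round to 0.50
(maximally uncertain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from acescreen.datasets import LabeledDataset
from acescreen.models import ModelConfig, fit, predict_proba
from acescreen.pseaac import PropertyTable, PseAACParams, encode_batch
from acescreen.seqio import Peptide, ProteinRecord

logger = logging.getLogger(__name__)

BINS = ("candidate", "mid_control", "zero_control", "other")
#: Probabilities within this distance of 0.00 / 0.50 round to the control
#: value at two decimals.
CONTROL_TOL = 0.005


@dataclass(frozen=True)
class KmerPeptide:
    """A substring of a source protein with 1-based inclusive coordinates."""

    sequence: str
    source_accession: str
    start: int  # 1-based inclusive
    k: int

    def __post_init__(self) -> None:
        if not (2 <= self.k <= 9):
            raise ValueError(f"k must be in [2, 9], got {self.k}")
        if len(self.sequence) != self.k:
            raise ValueError("sequence length must equal k")
        if self.start < 1:
            raise ValueError("start is 1-based and must be >= 1")

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.k - 1


@dataclass(frozen=True)
class ScreeningRecord:
    kmer: KmerPeptide
    probabilities: tuple[float, ...]
    candidate: bool
    bin: str

    @property
    def mean_probability(self) -> float:
        return float(np.mean(self.probabilities))


def kmer_cut(
    protein: ProteinRecord,
    k_min: int = 2,
    k_max: int = 9,
    dedupe: bool = True,
) -> list[KmerPeptide]:
    """All sliding-window substrings of lengths k_min..k_max, ordered by k then start.

    For a protein of length ``L >= k_max`` with the default range and no
    deduplication this yields ``sum_{k=2..9} (L-k+1) = 8L - 36`` k-mers.
    With ``dedupe`` (default), repeated sequences collapse to their first
    occurrence and the number removed is logged.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError(f"need 1 <= k_min <= k_max, got {k_min}..{k_max}")
    L = protein.length
    if L < k_min:
        logger.warning("protein %s (length %d) shorter than k_min=%d; no k-mers",
                       protein.accession, L, k_min)
        return []
    out: list[KmerPeptide] = []
    seen: set[str] = set()
    n_dup = 0
    for k in range(k_min, min(k_max, L) + 1):
        for start in range(L - k + 1):
            seq = protein.sequence[start:start + k]
            if dedupe:
                if seq in seen:
                    n_dup += 1
                    continue
                seen.add(seq)
            out.append(KmerPeptide(sequence=seq, source_accession=protein.accession,
                                   start=start + 1, k=k))
    if dedupe and n_dup:
        logger.info("kmer_cut(%s): collapsed %d duplicate k-mer(s)", protein.accession, n_dup)
    return out


def assign_bin(probabilities: Sequence[float], candidate_threshold: float = 0.99) -> str:
    """Bin a k-mer from its per-repeat probabilities (rules pinned at 2 decimals)."""
    p = np.asarray(probabilities, dtype=float)
    if (p > candidate_threshold).all():
        return "candidate"
    if (np.abs(p - 0.0) <= CONTROL_TOL).all():
        return "zero_control"
    if (np.abs(p - 0.5) <= CONTROL_TOL).all():
        return "mid_control"
    return "other"


def screen(
    proteins: Sequence[ProteinRecord],
    train_dataset: LabeledDataset,
    config: ModelConfig,
    n_repeats: int = 3,
    candidate_threshold: float = 0.99,
    seeds: Optional[Sequence[int]] = None,
    *,
    k_min: int = 2,
    k_max: int = 9,
    table: Optional[PropertyTable] = None,
    params: PseAACParams = PseAACParams(),
) -> list[ScreeningRecord]:
    """Score every k-mer of the input proteins across repeated training runs.

    Each repeat fits a fresh model on the full training dataset with its
    own seed and scores all k-mers; the candidate flag requires a
    probability above ``candidate_threshold`` in *every* repeat. Records
    are returned candidates first, then by mean probability descending.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seeds is None:
        seeds = list(range(n_repeats))
    seeds = [int(s) for s in seeds]
    if len(seeds) != n_repeats or len(set(seeds)) != n_repeats:
        raise ValueError(f"need {n_repeats} distinct seeds, got {seeds}")

    kmers: list[KmerPeptide] = []
    seen: set[str] = set()
    for prot in proteins:
        for km in kmer_cut(prot, k_min, k_max, dedupe=True):
            if km.sequence in seen:  # dedupe across proteins too
                continue
            seen.add(km.sequence)
            kmers.append(km)
    if not kmers:
        raise ValueError("no k-mers produced from the input proteins")

    peptides = [Peptide(id=f"{km.source_accession}:{km.start}-{km.end}", sequence=km.sequence)
                for km in kmers]
    X, ids, skipped = encode_batch(peptides, table, params)
    if skipped:
        logger.info("screen: skipped %d unencodable k-mer(s)", len(skipped))
    kept = {pid: i for i, pid in enumerate(ids)}
    kmers = [km for km, pep in zip(kmers, peptides) if pep.id in kept]

    X_tr, tr_ids, _ = encode_batch(list(train_dataset.peptides), table, params)
    kept_tr = set(tr_ids)
    y_tr = np.asarray(
        [l for p, l in zip(train_dataset.peptides, train_dataset.labels) if p.id in kept_tr],
        dtype=int,
    )
    prob_matrix = np.zeros((len(kmers), n_repeats))
    for r, rep_seed in enumerate(seeds):
        cfg = ModelConfig(config.family, dict(config.hyperparameters), seed=rep_seed)
        model = fit(cfg, X_tr, y_tr)
        prob_matrix[:, r] = predict_proba(model, X)

    records = []
    for i, km in enumerate(kmers):
        probs = tuple(float(v) for v in prob_matrix[i])
        b = assign_bin(probs, candidate_threshold)
        records.append(ScreeningRecord(kmer=km, probabilities=probs,
                                       candidate=(b == "candidate"), bin=b))
    records.sort(key=lambda r: (not r.candidate, -r.mean_probability))
    return records


def screening_report(
    records: Sequence[ScreeningRecord],
    top_n: Optional[int] = None,
    path: Optional[Union[str, Path]] = None,
) -> str:
    """Render screening records as a TSV table with per-bin counts in the header.

    Columns: sequence, source, position, k, one probability column per
    repeat, mean probability, bin. Returns the TSV text; optionally also
    writes it to ``path``.
    """
    if not records:
        raise ValueError("no screening records to report")
    counts = {b: sum(1 for r in records if r.bin == b) for b in BINS}
    n_rep = len(records[0].probabilities)
    lines = [
        "# bin counts: " + ", ".join(f"{b}={counts[b]}" for b in BINS),
        "\t".join(["sequence", "source", "start", "k"]
                  + [f"p{r + 1}" for r in range(n_rep)] + ["mean_p", "bin"]),
    ]
    shown = records if top_n is None else records[:top_n]
    for rec in shown:
        lines.append("\t".join(
            [rec.kmer.sequence, rec.kmer.source_accession, str(rec.kmer.start), str(rec.kmer.k)]
            + [f"{p:.4f}" for p in rec.probabilities]
            + [f"{rec.mean_probability:.4f}", rec.bin]
        ))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
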