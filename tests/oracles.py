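"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths (and numpy where
practical): standardization uses ``statistics.pstdev``, frequencies use
``str.count``, correlation factors are explicit Python loops, and AUC is
the O(n^2) count of concordant positive-negative score pairs.
"""

import csv
import statistics
from pathlib import Path

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_SCALES_TSV = Path(__file__).parent.parent / "src" / "acescreen" / "data" / "property_scales.tsv"


def load_standardized_scales() -> dict[str, dict[str, float]]:
    """Property name -> residue -> standardized value, computed independently."""
    with open(_SCALES_TSV, encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    header = rows[0]
    out: dict[str, dict[str, float]] = {}
    for row in rows[1:]:
        name = row[0]
        raw = {header[i]: float(row[i]) for i in range(1, len(row))}
        vals = [raw[aa] for aa in AA_ORDER]
        mean = statistics.fmean(vals)
        sd = statistics.pstdev(vals)
        out[name] = {aa: (raw[aa] - mean) / sd for aa in AA_ORDER}
    return out


def pseaac_oracle(sequence: str, scales: dict[str, dict[str, float]],
                  lambda_: int = 1, omega: float = 0.05) -> list[float]:
    """Type-II PseAAC vector by direct enumeration of frequencies and products."""
    L = len(sequence)
    assert L >= lambda_ + 1
    freqs = [sequence.count(aa) / L for aa in AA_ORDER]
    taus = []
    for lag in range(1, lambda_ + 1):
        for name in scales:  # insertion order == file order == property order
            h = scales[name]
            total = 0.0
            for j in range(L - lag):
                total += h[sequence[j]] * h[sequence[j + lag]]
            taus.append(total / (L - lag))
    denom = 1.0 + omega * sum(taus)
    return [f / denom for f in freqs] + [omega * t / denom for t in taus]


def auc_pair_counting(labels, scores) -> float:
    """Mann-Whitney concordance: P(score_pos > score_neg), ties counted 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    assert pos and neg
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def metrics_oracle(tp: int, tn: int, fp: int, fn: int) -> dict[str, float | None]:
    total = tp + tn + fp + fn
    return {
        "acc": (tn + tp) / total,
        "sens": tp / (tp + fn) if tp + fn else None,
        "spec": tn / (tn + fp) if tn + fp else None,
        "prec": tp / (tp + fp) if tp + fp else None,
    }
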