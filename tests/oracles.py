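"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's vectorized implementations: plain
Python loops over sorted prediction lists, explicit confusion-matrix counts,
and a rank-based AUC with tie correction.
"""

import numpy as np

from contourqa.uncertainty import MCPrediction, PredictionRecord


def make_record(uncertainty, true_label, predicted_label, structure="a", sample_id=None):
    mean_prob = 0.9 if predicted_label == 1 else 0.1
    return PredictionRecord(
        sample_id=sample_id or f"{structure}/{uncertainty:.6f}/{true_label}{predicted_label}",
        structure=structure,
        true_label=int(true_label),
        prediction=MCPrediction(
            per_pass_probs=(mean_prob,),
            mean_prob=mean_prob,
            entropy=float(uncertainty),
            predicted_label=int(predicted_label),
        ),
    )


def random_instance(rng, n, structure="a"):
    """Random predictions with at least one revision-required sample."""
    while True:
        true = rng.integers(0, 2, size=n)
        if true.sum() > 0:
            break
    pred = rng.integers(0, 2, size=n)
    u = rng.random(n)
    return [
        make_record(u[i], true[i], pred[i], structure=structure, sample_id=f"s{i:03d}")
        for i in range(n)
    ]


def curve_oracle(records):
    """Prefix-by-prefix cumulative recall via an explicit loop."""
    items = sorted(records, key=lambda r: (r.prediction.entropy, r.sample_id))
    recalls, fractions, uncertainties = [], [], []
    n_pos = 0
    n_tp = 0
    for i, r in enumerate(items):
        if r.true_label == 1:
            n_pos += 1
            if r.prediction.predicted_label == 1:
                n_tp += 1
        recalls.append(n_tp / n_pos if n_pos else 1.0)
        fractions.append((i + 1) / len(items))
        uncertainties.append(r.prediction.entropy)
    return uncertainties, recalls, fractions


def threshold_oracle(records, target):
    """First point (ascending uncertainty) whose cumulative recall < target."""
    u, recalls, _ = curve_oracle(records)
    for ui, ri in zip(u, recalls):
        if ri < target:
            return ui
    return 1.0


def recall_below(records, tau):
    pos = [r for r in records if r.true_label == 1 and r.prediction.entropy < tau]
    if not pos:
        return 1.0
    return sum(r.prediction.predicted_label == 1 for r in pos) / len(pos)


def metrics_oracle(true, scores):
    """Confusion-matrix metrics plus Mann-Whitney AUC with tie correction."""
    true = np.asarray(true)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= 0.5).astype(int)
    tp = int(((pred == 1) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    acc = (tp + tn) / len(true)
    rec = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    n_pos = int((true == 1).sum())
    n_neg = int((true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        auc = None
    else:
        from scipy.stats import rankdata

        ranks = rankdata(scores)  # average ranks handle ties
        auc = (ranks[true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {"accuracy": acc, "recall": rec, "precision": prec, "f1": f1, "auc": auc}


def binning_oracle(records, n_bins):
    """Histogram statistics via an explicit per-record loop."""
    bins = {}
    for r in records:
        b = min(int(r.prediction.entropy * n_bins), n_bins - 1)
        bins.setdefault(b, []).append(r)
    rows = {}
    for b, group in sorted(bins.items()):
        acc = np.mean([r.prediction.predicted_label == r.true_label for r in group])
        pos = [r for r in group if r.true_label == 1]
        recall = (np.mean([r.prediction.predicted_label == 1 for r in pos])
                  if pos else None)
        rows[b] = {
            "n": len(group),
            "mean_uncertainty": float(np.mean([r.prediction.entropy for r in group])),
            "accuracy": float(acc),
            "recall": None if recall is None else float(recall),
        }
    return rows
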