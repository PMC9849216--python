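"""The E-index: a pooled-control ending-preference score.

Healthy plasma cfDNA ends recur at preferred genomic positions.  The
ending-preference model counts, at every genomic locus, how often the
pooled control cohort's fragments end there — upstream (U) and
downstream (D) ends tallied separately and left unnormalised.  A
sample's E-index is the mean, over its N fragments, of

    M_U + M_D

where M_U is the pooled count at the fragment's U coordinate serving
as a U end and M_D likewise for its D coordinate; positions absent
from the model contribute zero.  Tumor-derived fragments end at
atypical positions, so cancer samples score lower.
"""

from __future__ import annotations

import dataclasses
import gzip
import os
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .core import FragmentSet

__all__ = [
    "EndingPreferenceModel",
    "EIndexResult",
    "build_end_model",
    "e_index",
    "evaluate_scores",
    "tumor_load_correlation",
    "combine_features",
]


@dataclasses.dataclass
class EndingPreferenceModel:
    """Sparse per-locus U/D end counts from pooled control fragments.

    ``u_positions``/``d_positions`` are sorted unique coordinates per
    chromosome with aligned raw counts.  The model is frozen once
    built; counts are deliberately not normalised (a single model
    scores every sample, so scale cancels in comparisons).
    """

    u_positions: dict[str, np.ndarray]
    u_counts: dict[str, np.ndarray]
    d_positions: dict[str, np.ndarray]
    d_counts: dict[str, np.ndarray]
    total_fragments: int
    samples: tuple[str, ...] = ()

    def total_u(self) -> int:
        return int(sum(c.sum() for c in self.u_counts.values()))

    def total_d(self) -> int:
        return int(sum(c.sum() for c in self.d_counts.values()))

    def _lookup(
        self, positions: np.ndarray, table_pos: np.ndarray, table_cnt: np.ndarray
    ) -> np.ndarray:
        idx = np.searchsorted(table_pos, positions)
        idx_c = np.clip(idx, 0, len(table_pos) - 1)
        hit = (idx < len(table_pos)) & (table_pos[idx_c] == positions)
        out = np.zeros(len(positions), dtype=np.int64)
        out[hit] = table_cnt[idx_c[hit]]
        return out

    def lookup_u(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        if chrom not in self.u_positions:
            return np.zeros(len(positions), dtype=np.int64)
        return self._lookup(positions, self.u_positions[chrom], self.u_counts[chrom])

    def lookup_d(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        if chrom not in self.d_positions:
            return np.zeros(len(positions), dtype=np.int64)
        return self._lookup(positions, self.d_positions[chrom], self.d_counts[chrom])

    # -- serialisation --------------------------------------------------
    def to_tsv(self, path: str | os.PathLike) -> None:
        """Sorted TSV (chrom, position, countU, countD)."""
        path = os.fspath(path)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write(f"#total_fragments={self.total_fragments}\n")
            for chrom in sorted(set(self.u_positions) | set(self.d_positions)):
                up = self.u_positions.get(chrom, np.empty(0, np.int64))
                uc = self.u_counts.get(chrom, np.empty(0, np.int64))
                dp = self.d_positions.get(chrom, np.empty(0, np.int64))
                dc = self.d_counts.get(chrom, np.empty(0, np.int64))
                merged = np.union1d(up, dp)
                u_all = self._lookup(merged, up, uc)
                d_all = self._lookup(merged, dp, dc)
                for pos, u, d in zip(merged, u_all, d_all):
                    fh.write(f"{chrom}\t{pos}\t{u}\t{d}\n")

    @staticmethod
    def from_tsv(path: str | os.PathLike) -> "EndingPreferenceModel":
        path = os.fspath(path)
        opener = gzip.open if path.endswith(".gz") else open
        total = 0
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if line.startswith("#total_fragments="):
                        total = int(line.split("=", 1)[1])
                    continue
                chrom, pos, u, d = line.split("\t")
                per_chrom.setdefault(chrom, []).append((int(pos), int(u), int(d)))
        up, uc, dp, dc = {}, {}, {}, {}
        for chrom, rows in per_chrom.items():
            arr = np.array(rows, dtype=np.int64)
            u_mask = arr[:, 1] > 0
            d_mask = arr[:, 2] > 0
            up[chrom] = arr[u_mask, 0]
            uc[chrom] = arr[u_mask, 1]
            dp[chrom] = arr[d_mask, 0]
            dc[chrom] = arr[d_mask, 2]
        return EndingPreferenceModel(up, uc, dp, dc, total_fragments=total)


@dataclasses.dataclass
class EIndexResult:
    sample_id: str
    n_fragments: int
    e_index: float
    missing_ends: int


def _end_counts(sets: Sequence[FragmentSet], attr: str) -> tuple[dict, dict]:
    by_chrom: dict[str, list[np.ndarray]] = {}
    for fs in sets:
        ends = getattr(fs, attr)
        chroms = fs.chroms.astype(str)
        for chrom in np.unique(chroms):
            by_chrom.setdefault(chrom, []).append(ends[chroms == chrom])
    positions, counts = {}, {}
    for chrom, chunks in by_chrom.items():
        pos, cnt = np.unique(np.concatenate(chunks), return_counts=True)
        positions[chrom] = pos
        counts[chrom] = cnt
    return positions, counts


def build_end_model(controls: Sequence[FragmentSet]) -> EndingPreferenceModel:
    """Accumulate U/D end counts over pooled, deduplicated control sets."""
    controls = list(controls)
    if not controls or all(len(fs) == 0 for fs in controls):
        raise ValueError("cannot build an ending-preference model from an empty pool")
    up, uc = _end_counts(controls, "u_ends")
    dp, dc = _end_counts(controls, "d_ends")
    return EndingPreferenceModel(
        u_positions=up,
        u_counts=uc,
        d_positions=dp,
        d_counts=dc,
        total_fragments=sum(len(fs) for fs in controls),
        samples=tuple(fs.sample_id for fs in controls),
    )


def e_index(sample: FragmentSet, model: EndingPreferenceModel) -> EIndexResult:
    """Score one (deduplicated) sample against the control model."""
    if len(sample) == 0:
        raise ValueError("cannot score an empty sample")
    chroms = sample.chroms.astype(str)
    weights = np.zeros(len(sample), dtype=np.float64)
    found = np.zeros(2 * len(sample), dtype=bool)
    cursor = 0
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        mu = model.lookup_u(chrom, sample.u_ends[mask])
        md = model.lookup_d(chrom, sample.d_ends[mask])
        weights[mask] = mu + md
        n = int(mask.sum())
        found[cursor : cursor + n] = mu > 0
        found[cursor + n : cursor + 2 * n] = md > 0
        cursor += 2 * n
    return EIndexResult(
        sample_id=sample.sample_id,
        n_fragments=len(sample),
        e_index=float(weights.mean()),
        missing_ends=int((~found).sum()),
    )


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str = "cancer",
) -> dict[str, float]:
    """ROC evaluation under the convention that lower scores mean cancer.

    Returns the AUC, a two-sided Z-test P against AUC = 0.5 (Hanley &
    McNeil standard error) and a two-sided Mann–Whitney U P between the
    two groups.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    y = labels == positive_label
    if y.all() or not y.any():
        raise ValueError("both labels must be present")
    auc = float(roc_auc_score(y.astype(int), -scores))
    se = _hanley_mcneil_se(auc, int(y.sum()), int((~y).sum()))
    if se == 0.0:
        z_p = 0.0 if auc != 0.5 else 1.0
    else:
        z = (auc - 0.5) / se
        z_p = float(2 * stats.norm.sf(abs(z)))
    mwu = stats.mannwhitneyu(scores[y], scores[~y], alternative="two-sided")
    return {"auc": auc, "z_p": z_p, "mannwhitney_p": float(mwu.pvalue)}


def tumor_load_correlation(
    scores: Sequence[float], tumor_fractions: Sequence[float]
) -> tuple[float, float]:
    """Pearson r between score and tumor DNA load, with two-sided P."""
    scores = np.asarray(scores, dtype=np.float64)
    fractions = np.asarray(tumor_fractions, dtype=np.float64)
    if len(scores) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.allclose(scores.std(), 0.0) or np.allclose(fractions.std(), 0.0):
        import warnings

        warnings.warn("constant input; correlation undefined")
        return float("nan"), float("nan")
    res = stats.pearsonr(scores, fractions)
    return float(res.statistic), float(res.pvalue)


def combine_features(
    methylation_density: Sequence[float],
    e_index_values: Sequence[float],
    labels: Sequence[str],
    positive_label: str = "cancer",
) -> dict[str, object]:
    """Two-feature logistic combination scored by leave-one-out.

    Each held-out sample is scored by a logistic regression fitted on
    the remaining samples (features standardised on the training
    fold); the combined AUC uses the held-out cancer probabilities.
    Individual AUCs use the lower-score-means-cancer convention.
    """
    md = np.asarray(methylation_density, dtype=np.float64)
    ei = np.asarray(e_index_values, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    if not (len(md) == len(ei) == len(labels)):
        raise ValueError("feature and label lists must align")
    y = (labels == positive_label).astype(int)
    X = np.column_stack([md, ei])
    n = len(y)
    loo_scores = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(max_iter=1000)
        clf.fit((X[train] - mu) / sd, y[train])
        loo_scores[i] = clf.predict_proba(((X[i] - mu) / sd).reshape(1, -1))[0, 1]
    return {
        "auc_methylation": float(roc_auc_score(y, -md)),
        "auc_e_index": float(roc_auc_score(y, -ei)),
        "auc_combined": float(roc_auc_score(y, loo_scores)),
        "combined_scores": loo_scores,
    }
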