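"""Marker-trait association scanning for SVs and SNPs.

The scan fits, per marker, an ordinary least squares model
``phenotype ~ genotype + PC covariates`` (the principal components of the
genotype matrix absorb population structure), reporting the effect beta,
its standard error, a two-sided t-test p-value, the minor allele frequency
and the phenotypic variance explained

    PVE = beta^2 / (beta^2 + N * se^2)

(the 2*MAF*(1-MAF) factor common to numerator and denominator cancels).
The genome-wide threshold is 1/n_eff with n_eff the number of markers
surviving windowed LD pruning (window 50 markers, step 5, r^2 > 0.1
removes the lower-MAF member of a pair).  Significant markers cluster
into QTL peaks, and SNP-based vs SV-based peaks are compared with a
flanking-distance overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1


@dataclass
class MarkerSet:
    """Markers x samples dosage matrix with positions and classes.

    Values are 0/1 for SV presence/absence or 0/1/2 for SNP dosage;
    -1 marks a missing call.
    """

    genotypes: pd.DataFrame
    positions: pd.Series | None = None
    chroms: pd.Series | None = None
    classes: pd.Series | None = None  # 'SNP' or 'SV' per marker

    def __post_init__(self) -> None:
        idx = self.genotypes.index
        if self.positions is None:
            self.positions = pd.Series(np.arange(len(idx)), index=idx)
        if self.chroms is None:
            self.chroms = pd.Series("chr1", index=idx)
        if self.classes is None:
            self.classes = pd.Series("SV", index=idx)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def _masked(self) -> np.ndarray:
        g = self.genotypes.to_numpy(dtype=float)
        return np.where(g == MISSING, np.nan, g)

    def maf(self) -> pd.Series:
        g = self._masked()
        ploidy = 2.0 if np.nanmax(g, initial=0.0) > 1 else 1.0
        with np.errstate(invalid="ignore"):
            f = np.nanmean(g, axis=1) / ploidy
        maf = np.minimum(f, 1.0 - f)
        return pd.Series(np.nan_to_num(maf), index=self.genotypes.index)

    def missing_rate(self) -> pd.Series:
        g = self.genotypes.to_numpy()
        return pd.Series((g == MISSING).mean(axis=1), index=self.genotypes.index)

    def subset(self, markers) -> "MarkerSet":
        return MarkerSet(
            genotypes=self.genotypes.loc[markers],
            positions=self.positions.loc[markers],
            chroms=self.chroms.loc[markers],
            classes=self.classes.loc[markers],
        )

    def imputed(self) -> np.ndarray:
        """Missing calls replaced by the per-marker mean dosage."""
        g = self._masked()
        mean = np.nanmean(np.where(np.isnan(g).all(axis=1, keepdims=True), 0, g),
                          axis=1, keepdims=True)
        mean = np.nan_to_num(mean)
        return np.where(np.isnan(g), np.broadcast_to(mean, g.shape), g)


def filter_markers(markers: MarkerSet, maf_min: float = 0.01,
                   missing_max: float = 0.1) -> MarkerSet:
    """Keep markers with MAF strictly above and missing rate strictly below."""
    maf = markers.maf()
    miss = markers.missing_rate()
    keep = markers.genotypes.index[(maf > maf_min) & (miss < missing_max)]
    return markers.subset(keep)


def pca_covariates(markers: MarkerSet, n_components: int = 5) -> np.ndarray:
    """Top principal components of the centred genotype matrix (samples x k).

    Missing genotypes are mean-imputed per marker before the decomposition.
    Component signs follow the largest-|score| convention so results are
    deterministic.
    """
    if markers.n_samples < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} samples for {n_components} PCs")
    x = markers.imputed().T  # samples x markers
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("genotype matrix has no variance; PCs undefined")
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def pve(beta: float, se: float, maf: float, n: int) -> float:
    """Phenotypic variance explained by one marker.

    Computed from effect size, its standard error, MAF and sample size:
    2 beta^2 MAF(1-MAF) over itself plus 2 N se^2 MAF(1-MAF); the MAF
    factor cancels, leaving beta^2 / (beta^2 + N se^2).
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if not 0 < maf < 1:
        raise ValueError("MAF must be strictly inside (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    het = maf * (1.0 - maf)
    num = 2.0 * beta * beta * het
    den = num + (se * se) * 2.0 * n * het
    return num / den


@dataclass
class QTLPeak:
    chrom: str
    lead_pos: int
    lead_marker: str
    lead_p: float
    source: str                       # 'SNP' or 'SV'
    members: list[str] = field(default_factory=list)


class AssociationResults:
    """Per-marker estimates with summary and peak calling."""

    def __init__(self, table: pd.DataFrame, n_samples: int):
        self.table = table
        self.n_samples = n_samples

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p").head(top)
        lines = ["Association scan: %d markers, %d samples"
                 % (len(self.table), self.n_samples),
                 f"{'marker':<16}{'class':<6}{'beta':>10}{'se':>10}"
                 f"{'p':>12}{'maf':>8}{'pve':>8}"]
        for m, r in t.iterrows():
            lines.append(f"{m:<16}{r['class']:<6}{r['beta']:>10.4f}"
                         f"{r['se']:>10.4f}{r['p']:>12.3e}"
                         f"{r['maf']:>8.3f}{r['pve']:>8.3f}")
        return "\n".join(lines)

    def peaks(self, threshold: float, window: int = 800_000,
              source: str | None = None) -> list[QTLPeak]:
        return call_peaks(self.table, threshold, window, source=source)


class AssociationModel:
    """OLS association scan of every marker against one phenotype.

    Parameters
    ----------
    markers : MarkerSet
    phenotype : pd.Series indexed by sample
    covariates : array (samples x k) or None
        Typically ``pca_covariates(markers, 5)``.
    """

    def __init__(self, markers: MarkerSet, phenotype: pd.Series,
                 covariates: np.ndarray | None = None):
        if len(phenotype) != markers.n_samples:
            raise ValueError("phenotype length != sample count")
        self.markers = markers
        self.phenotype = phenotype.reindex(markers.genotypes.columns)
        if self.phenotype.isna().any():
            raise ValueError("phenotype missing for some samples")
        self.covariates = covariates

    @classmethod
    def from_dataframe(cls, genotypes: pd.DataFrame, phenotype: pd.Series,
                       n_pcs: int = 5, **marker_kwargs) -> "AssociationModel":
        ms = MarkerSet(genotypes, **marker_kwargs)
        cov = pca_covariates(ms, n_pcs) if n_pcs > 0 else None
        return cls(ms, phenotype, covariates=cov)

    def fit(self) -> AssociationResults:
        y_all = self.phenotype.to_numpy(dtype=float)
        g_all = self.markers.genotypes.to_numpy(dtype=float)
        maf = self.markers.maf()
        rows = []
        for i, marker in enumerate(self.markers.genotypes.index):
            g = g_all[i]
            keep = g != MISSING
            gi, yi = g[keep], y_all[keep]
            n = int(keep.sum())
            if n < 3 or np.ptp(gi) == 0:
                continue  # monomorphic after missing-drop: skip
            cols = [np.ones(n), gi]
            if self.covariates is not None:
                cols.extend(self.covariates[keep].T)
            x = np.column_stack(cols)
            dof = n - x.shape[1]
            if dof < 1:
                continue
            xtx_inv = np.linalg.pinv(x.T @ x)
            beta_vec = xtx_inv @ (x.T @ yi)
            resid = yi - x @ beta_vec
            sigma2 = float(resid @ resid) / dof
            se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
            beta = float(beta_vec[1])
            if se == 0.0:
                p = 1.0 if beta == 0 else 0.0
            else:
                t = beta / se
                p = float(2.0 * stats.t.sf(abs(t), dof))
            m = float(maf.loc[marker])
            v = pve(beta, se, m, n) if (se > 0 and 0 < m < 1) else np.nan
            rows.append((marker, self.markers.classes.loc[marker],
                         self.markers.chroms.loc[marker],
                         int(self.markers.positions.loc[marker]),
                         beta, se, p, m, n, v))
        table = pd.DataFrame(
            rows, columns=["marker", "class", "chrom", "pos", "beta", "se",
                           "p", "maf", "n", "pve"]).set_index("marker")
        return AssociationResults(table, self.markers.n_samples)


def association_scan(markers: MarkerSet, phenotype: pd.Series,
                     covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Functional wrapper around :class:`AssociationModel`."""
    return AssociationModel(markers, phenotype, covariates).fit().table


def effective_tests(markers: MarkerSet, window: int = 50, step: int = 5,
                    r2_max: float = 0.1) -> tuple[int, float]:
    """LD-pruned marker count and the derived 1/n genome-wide threshold.

    Windowed greedy pruning: within each ``window``-marker window (slid by
    ``step``), for any surviving pair with squared Pearson correlation of
    mean-imputed dosages above ``r2_max``, the lower-MAF marker is removed.
    """
    order = np.lexsort((self_pos := markers.positions.to_numpy(),
                        markers.chroms.to_numpy().astype(str)))
    del self_pos
    idx = markers.genotypes.index.to_numpy()[order]
    g = markers.imputed()[order]
    maf = markers.maf().to_numpy()[order]
    n = len(idx)
    removed = np.zeros(n, dtype=bool)
    start = 0
    while start < n:
        stop = min(start + window, n)
        live = [i for i in range(start, stop) if not removed[i]]
        for a_i in range(len(live)):
            for b_i in range(a_i + 1, len(live)):
                i, j = live[a_i], live[b_i]
                if removed[i] or removed[j]:
                    continue
                gi, gj = g[i], g[j]
                if np.std(gi) == 0 or np.std(gj) == 0:
                    continue
                r = np.corrcoef(gi, gj)[0, 1]
                if r * r > r2_max:
                    # keep the higher-MAF marker; ties keep the earlier one
                    if maf[i] >= maf[j]:
                        removed[j] = True
                    else:
                        removed[i] = True
        if stop == n:
            break
        start += step
    n_eff = int((~removed).sum())
    return n_eff, 1.0 / n_eff if n_eff else float("inf")


def call_peaks(results: pd.DataFrame, threshold: float,
               window: int = 800_000, source: str | None = None) -> list[QTLPeak]:
    """Cluster significant markers within ``window`` bp into QTL peaks."""
    t = results
    if source is not None:
        t = t[t["class"] == source]
    sig = t[t["p"] < threshold].sort_values(["chrom", "pos"])
    peaks: list[QTLPeak] = []
    cur: list[tuple[str, str, int, float]] = []  # (marker, chrom, pos, p)

    def flush() -> None:
        if not cur:
            return
        lead = min(cur, key=lambda r: (r[3], r[2]))
        peaks.append(QTLPeak(
            chrom=lead[1], lead_pos=lead[2], lead_marker=lead[0],
            lead_p=lead[3], source=str(t.loc[lead[0], "class"]),
            members=[r[0] for r in cur]))

    for marker, row in sig.iterrows():
        rec = (marker, str(row["chrom"]), int(row["pos"]), float(row["p"]))
        if cur and (rec[1] != cur[-1][1] or rec[2] - cur[-1][2] > window):
            flush()
            cur = []
        cur.append(rec)
    flush()
    return peaks


def classify_peak_overlap(snp_peaks: list[QTLPeak], sv_peaks: list[QTLPeak],
                          flank: int = 800_000) -> dict[str, list[QTLPeak]]:
    """Partition peaks into snp_only / sv_only / both by lead proximity.

    A peak is 'both' iff some peak of the other class lies within ``flank``
    bp of its lead on the same chromosome.
    """
    def near(p: QTLPeak, others: list[QTLPeak]) -> bool:
        return any(o.chrom == p.chrom and abs(o.lead_pos - p.lead_pos) <= flank
                   for o in others)

    out: dict[str, list[QTLPeak]] = {"snp_only": [], "sv_only": [], "both": []}
    for p in snp_peaks:
        (out["both"] if near(p, sv_peaks) else out["snp_only"]).append(p)
    for p in sv_peaks:
        (out["both"] if near(p, snp_peaks) else out["sv_only"]).append(p)
    assert (len(out["snp_only"]) + len(out["sv_only"]) + len(out["both"])
            == len(snp_peaks) + len(sv_peaks))
    return out


def relative_expression(ct_target_test: float, ct_reference_test: float,
                        ct_target_control: float,
                        ct_reference_control: float) -> float:
    """qPCR fold change, R = 2^-ddCt.

    ddCt = (Ct_target - Ct_reference) in the test sample minus the same
    difference in the control sample.
    """
    for v in (ct_target_test, ct_reference_test, ct_target_control,
              ct_reference_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_reference_test) - \
           (ct_target_control - ct_reference_control)
    return float(2.0 ** (-ddct))
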