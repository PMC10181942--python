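"""LTR retrotransposon insertion-time dating.

The two long terminal repeats of an element are identical at insertion and
accumulate substitutions independently afterwards, so their divergence K
dates the insertion as T = K / (2 mu).  K defaults to the uncorrected
p-distance between the aligned 5' and 3' LTRs (gap and N columns excluded
from both numerator and denominator); the Jukes-Cantor correction
-(3/4) ln(1 - 4p/3) is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

#: per-site, per-year base substitution rate used for Solanum dating
DEFAULT_MU = 1.3e-8


@dataclass
class LTRElement:
    element_id: str
    genome: str
    seq5: str
    seq3: str
    superfamily: str = "unknown"
    K: float | None = None
    T: float | None = None  # years


def _aligned_pair(seq5: str, seq3: str) -> tuple[str, str]:
    """Globally align the two LTRs when lengths differ (edlib path)."""
    if len(seq5) == len(seq3):
        return seq5, seq3
    res = edlib.align(seq5, seq3, task="path")
    nice = edlib.getNiceAlignment(res, seq5, seq3)
    return nice["query_aligned"], nice["target_aligned"]


def ltr_pair_distance(seq5: str, seq3: str, method: str = "uncorrected") -> float:
    """Genetic distance K between the two ends of an element.

    ``uncorrected``: mismatches / compared sites.  ``jc69``: Jukes-Cantor
    correction of that proportion; NaN when p >= 0.75 (undefined).
    Columns containing a gap or an N are excluded entirely.
    """
    if not seq5 or not seq3:
        raise ValueError("LTR sequences must be non-empty")
    a, b = _aligned_pair(seq5.upper(), seq3.upper())
    compared = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable sites between the two LTRs")
    p = mismatches / compared
    if method == "uncorrected":
        return p
    if method == "jc69":
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    raise ValueError(f"unknown method {method!r}")


def insertion_time(K: float, mu: float = DEFAULT_MU) -> float:
    """Insertion age in years: T = K / (2 mu)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / (2.0 * mu)


def date_elements(elements: list[LTRElement], mu: float = DEFAULT_MU,
                  method: str = "uncorrected") -> pd.DataFrame:
    """K and T for every element; also stored back on the records."""
    rows = []
    for el in elements:
        el.K = ltr_pair_distance(el.seq5, el.seq3, method=method)
        el.T = insertion_time(el.K, mu) if not math.isnan(el.K) else float("nan")
        rows.append((el.element_id, el.genome, el.superfamily, el.K, el.T))
    return pd.DataFrame(
        rows, columns=["element", "genome", "superfamily", "K", "T_years"]
    ).set_index("element")


def insertion_time_profile(dated: pd.DataFrame,
                           bin_width: float = 250_000.0) -> pd.DataFrame:
    """Histogram of insertion times per (genome, superfamily).

    Returns long-format counts with the bin's lower edge in years plus a
    ``mode`` column marking each profile's modal bin (amplification burst
    candidate).
    """
    if dated.empty:
        raise ValueError("no dated elements")
    d = dated.dropna(subset=["T_years"]).copy()
    d["bin_start"] = (d["T_years"] // bin_width) * bin_width
    out = (d.groupby(["genome", "superfamily", "bin_start"])
            .size().rename("count").reset_index())
    out["mode"] = False
    for (_g, _s), grp in out.groupby(["genome", "superfamily"]):
        top = grp["count"].idxmax()
        out.loc[top, "mode"] = True
    return out


def modal_age(dated: pd.DataFrame, bin_width: float = 250_000.0,
              genome: str | None = None,
              superfamily: str | None = None) -> float:
    """Midpoint (years) of the most occupied insertion-time bin."""
    prof = insertion_time_profile(dated, bin_width)
    if genome is not None:
        prof = prof[prof["genome"] == genome]
    if superfamily is not None:
        prof = prof[prof["superfamily"] == superfamily]
    agg = prof.groupby("bin_start")["count"].sum()
    start = float(agg.idxmax())
    return start + bin_width / 2.0


def elements_from_truth(truth) -> list[LTRElement]:
    """Adapt the simulator's LTR records into datable elements."""
    return [LTRElement(t.element_id, t.genome, t.seq5, t.seq3, t.superfamily)
            for t in truth.ltr_elements]


def read_ltr_tsv(path) -> list[LTRElement]:
    df = pd.read_csv(path, sep="\t")
    need = {"element", "seq5", "seq3"}
    if not need <= set(df.columns):
        raise ValueError(f"LTR table needs columns {sorted(need)}")
    return [LTRElement(r["element"], str(r.get("genome", "na")),
                       r["seq5"], r["seq3"],
                       str(r.get("superfamily", "unknown")))
            for _, r in df.iterrows()]


def write_ltr_tables(out_prefix: str, dated: pd.DataFrame,
                     bin_width: float = 250_000.0) -> None:
    dated.to_csv(f"{out_prefix}.elements.tsv", sep="\t")
    insertion_time_profile(dated, bin_width).to_csv(
        f"{out_prefix}.profile.tsv", sep="\t", index=False)


def jc69_vs_uncorrected(p: float) -> tuple[float, float]:
    """Convenience for the correction-dominance property: (p, jc69(p))."""
    return p, -0.75 * np.log1p(-4.0 * p / 3.0)
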