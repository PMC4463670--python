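"""Two-library differential expression on miRNA read counts.

Normalisation is reads-per-million against the library's clean-read total:
NE = count / total x 1e6.  A zero NE is floored to 0.01 so the log2 ratio is
always defined; miRNAs below NE 1 in both libraries, or below the raw-count
floor in both, are excluded as too weak to call.  Significance uses the
Audic-Claverie exact conditional test for a single count observed in each of
two libraries: given x reads in library A, the probability of seeing y reads
in library B under equal underlying proportion is

    p(y | x) = (N_B/N_A)^y (x+y)! / ( x! y! (1 + N_B/N_A)^(x+y+1) )

which is the negative binomial NB(y; x+1, N_A/(N_A+N_B)).  The two-sided
p-value doubles the smaller tail, capped at 1.  A miRNA is called
differential when |log2(NE_B/NE_A)| >= fc_threshold and p <= p_threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STATUSES = ("significant_up", "significant_down", "not_significant", "filtered_low")


@dataclass
class DEConfig:
    min_reads: int = 100  # discard miRNAs below this raw count in both libraries
    ne_floor: float = 0.01  # replacement for NE == 0
    ne_min: float = 1.0  # removed when NE below this in both libraries
    fc_threshold: float = 1.0  # on |log2(NE_B/NE_A)|
    p_threshold: float = 0.01
    bh: bool = False  # optional Benjamini-Hochberg on non-filtered rows

    def validate(self) -> None:
        for name in ("min_reads", "ne_floor", "ne_min", "fc_threshold", "p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def normalize(count: float, total: float) -> float:
    """Reads-per-million normalised expression."""
    if total <= 0:
        raise ValueError("library total must be > 0")
    if count < 0 or count > total:
        raise ValueError("count must satisfy 0 <= count <= total")
    return count / total * 1_000_000.0


def count_pvalue(x: int, y: int, n_a: float, n_b: float) -> float:
    """Two-sided Audic-Claverie exact p-value for counts (x, y)."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library totals must be positive")
    return float(count_pvalues(np.array([x]), np.array([y]), n_a, n_b)[0])


def count_pvalues(x: np.ndarray, y: np.ndarray, n_a: float, n_b: float) -> np.ndarray:
    """Vectorised two-sided AC p-values; y | x ~ NB(x+1, N_A/(N_A+N_B)).

    The conditioning orientation is canonicalised (condition on the smaller
    (count, total) pair) so that the statistic is invariant under swapping
    the two libraries, making the report orientation-free.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library totals must be positive")
    na = np.full(x.shape, float(n_a))
    nb = np.full(y.shape, float(n_b))
    swap = (y < x) | ((y == x) & (nb < na))
    cx = np.where(swap, y, x)
    cy = np.where(swap, x, y)
    cna = np.where(swap, nb, na)
    cnb = np.where(swap, na, nb)
    p0 = cna / (cna + cnb)
    lower = stats.nbinom.cdf(cy, cx + 1, p0)  # P(Y <= y)
    upper = stats.nbinom.sf(cy - 1, cx + 1, p0)  # P(Y >= y)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def build_table(
    counts: dict[str, tuple[int, int]], total_a: float, total_b: float
) -> pd.DataFrame:
    """Expression table from raw per-miRNA counts and library totals."""
    rows = [
        {"name": name, "count_A": int(a), "count_B": int(b)}
        for name, (a, b) in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["name", "count_A", "count_B"])
    df["NE_A"] = [normalize(c, total_a) for c in df["count_A"]]
    df["NE_B"] = [normalize(c, total_b) for c in df["count_B"]]
    df.attrs["total_A"] = total_a
    df.attrs["total_B"] = total_b
    return df


def adjust_and_filter(table: pd.DataFrame, config: DEConfig | None = None) -> pd.DataFrame:
    """Apply the NE floor then the two weak-expression filters, in order.

    1. NE of exactly 0 -> ne_floor (0.01);
    2. NE below ne_min in both libraries -> filtered_low;
    3. raw count below min_reads in both libraries -> filtered_low.
    """
    config = config or DEConfig()
    config.validate()
    df = table.copy()
    for col in ("NE_A", "NE_B"):
        df[col] = df[col].where(df[col] != 0.0, config.ne_floor)
    low_ne = (df["NE_A"] < config.ne_min) & (df["NE_B"] < config.ne_min)
    low_reads = df[["count_A", "count_B"]].max(axis=1) < config.min_reads
    df["status"] = np.where(low_ne | low_reads, "filtered_low", "not_significant")
    df["log2ratio"] = np.log2(df["NE_B"] / df["NE_A"])  # B over A
    return df


def call_de(
    table: pd.DataFrame, config: DEConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Significance calls on an adjusted table; returns (table, summary).

    ``significant_up`` means higher in library B (log2ratio > 0).
    """
    config = config or DEConfig()
    df = table if "status" in table.columns else adjust_and_filter(table, config)
    df = df.copy()
    total_a = df.attrs.get("total_A") or table.attrs.get("total_A")
    total_b = df.attrs.get("total_B") or table.attrs.get("total_B")
    df["pvalue"] = count_pvalues(
        df["count_A"].to_numpy(), df["count_B"].to_numpy(), total_a, total_b
    )
    p_eff = df["pvalue"].copy()
    if config.bh:
        keep = df["status"] != "filtered_low"
        p_eff.loc[keep] = _benjamini_hochberg(df.loc[keep, "pvalue"].to_numpy())
        df["padj"] = np.nan
        df.loc[keep, "padj"] = p_eff.loc[keep]
    sig = (
        (df["status"] != "filtered_low")
        & (df["log2ratio"].abs() >= config.fc_threshold)
        & (p_eff <= config.p_threshold)
    )
    df.loc[sig & (df["log2ratio"] > 0), "status"] = "significant_up"
    df.loc[sig & (df["log2ratio"] < 0), "status"] = "significant_down"
    summary = {
        "n_tested": int((df["status"] != "filtered_low").sum()),
        "n_significant": int(sig.sum()),
        "n_up_in_B": int((df["status"] == "significant_up").sum()),
        "n_up_in_A": int((df["status"] == "significant_down").sum()),
    }
    return df, summary


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def scatter_table(table: pd.DataFrame) -> pd.DataFrame:
    """Log2-expression scatter source: exactly the non-filtered rows."""
    df = table[table["status"] != "filtered_low"].copy()
    df["log2_NE_A"] = np.log2(df["NE_A"])
    df["log2_NE_B"] = np.log2(df["NE_B"])
    return df.reset_index(drop=True)


# --- count-level simulation helpers (calibration / recovery experiments) ---


def simulate_two_library_counts(
    n_mirnas: int = 200,
    depth: int = 100_000,
    de_fraction: float = 0.1,
    log2fc: float = 2.0,
    sigma: float = 0.8,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multinomial counts for two libraries with a known DE subset.

    Returns (x, y, true_log2fc) arrays; true_log2fc is 0 for null miRNAs and
    alternates sign over the DE subset.
    """
    rng = rng or np.random.default_rng()
    base = rng.lognormal(0.0, sigma, n_mirnas)
    truth = np.zeros(n_mirnas)
    n_de = int(round(de_fraction * n_mirnas))
    de_idx = rng.choice(n_mirnas, size=n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    truth[np.sort(de_idx)] = signs * log2fc
    w_a = base
    w_b = base * 2.0**truth
    x = rng.multinomial(depth, w_a / w_a.sum())
    y = rng.multinomial(depth, w_b / w_b.sum())
    return x, y, truth


def null_pvalue_fraction(
    n_mirnas: int = 100,
    depth: int = 100_000,
    n_reps: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Pooled fraction of p <= alpha under equal-proportion null libraries."""
    rng = rng or np.random.default_rng()
    props = rng.dirichlet(np.ones(n_mirnas))
    x = rng.multinomial(depth, props, size=n_reps)
    y = rng.multinomial(depth, props, size=n_reps)
    p = count_pvalues(x.ravel(), y.ravel(), depth, depth)
    return float((p <= alpha).mean())


def de_recovery(
    n_mirnas: int = 200,
    depth: int = 100_000,
    de_fraction: float = 0.1,
    log2fc: float = 2.0,
    config: DEConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Sensitivity and false-positive rate of the DE caller on known truth."""
    config = config or DEConfig()
    x, y, truth = simulate_two_library_counts(
        n_mirnas, depth, de_fraction, log2fc, rng=rng
    )
    counts = {f"m{i}": (int(x[i]), int(y[i])) for i in range(n_mirnas)}
    table = build_table(counts, depth, depth)
    table, _ = call_de(table, config)
    called = table["status"].str.startswith("significant").to_numpy()
    is_de = truth != 0.0
    sens = called[is_de].mean() if is_de.any() else float("nan")
    fpr = called[~is_de].mean() if (~is_de).any() else float("nan")
    return {"sensitivity": float(sens), "fpr": float(fpr), "n_de": int(is_de.sum())}
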