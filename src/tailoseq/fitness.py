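"""Strain- and gene-level fitness from barcode counts.

Pooled barcoded transposon mutant libraries are sequenced before (Time0)
and after growth under selection; the change in each barcode's relative
abundance measures the fitness effect of disrupting the gene it sits in.
This module turns raw barcode counts into normalized strain fitness
values, inverse-variance-weighted gene fitness, a moderated t-like
statistic, and replicate averages.

Estimator, fixed here once and used everywhere:

* raw strain ratio   r_s = log2((n_after + 1) / (n_0 + 1))
* usability filter   0.1 <= gene_fraction <= 0.9 and n_0 >= 3
* normalization      f_s = r_s - m, where m is the median over genes of
  the preliminary (unnormalized) weighted-mean gene fitness in the sample
* weights            w_s = 1 / v_s,
                     v_s = (1/ln 2)^2 (1/(1+n_after) + 1/(1+n_0))
* gene fitness       f_g = sum(w_s f_s) / sum(w_s) over used strains
* t-like statistic   t = f_g / sqrt(V_g + sigma0^2), sigma0 = 0.1,
                     V_g = max(V_count, V_between)

The pseudocount of 1 keeps ratios finite at zero counts; the per-sample
median normalization removes sequencing-depth and global-growth shifts so
that a typical (unselected) gene scores 0; the variance floor sigma0
prevents tiny counting variances from inflating t.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import EmptyAssayError, PairingError

__all__ = [
    "SIGMA0",
    "strain_fitness",
    "gene_fitness",
    "t_statistic",
    "average_replicates",
    "fit_assay",
]

#: variance floor added to the gene variance inside the t denominator
SIGMA0 = 0.1

_LOG2_SQ = (1.0 / math.log(2.0)) ** 2

#: central insertion window: fraction of gene length from the start codon
CENTRAL_WINDOW = (0.1, 0.9)

#: minimum Time0 read count for a strain to be used
MIN_TIME0_READS = 3


def strain_fitness(
    pool: pd.DataFrame,
    n0: pd.Series,
    n_after: pd.Series,
) -> pd.DataFrame:
    """Per-strain normalized fitness for one treated/Time0 sample pair.

    Parameters
    ----------
    pool
        Mutant pool table with one row per barcode and columns
        ``barcode``, ``locus_tag``, ``gene_fraction``.
    n0, n_after
        Read counts indexed by barcode for the Time0 and the treated
        sample. Barcodes present in the pool but missing from a count
        vector are treated as count 0.

    Returns
    -------
    DataFrame indexed like ``pool`` with columns ``barcode``,
    ``locus_tag``, ``n0``, ``n_after``, ``r_raw``, ``f_s``, ``w_s``,
    ``used``.
    """
    barcodes = pool["barcode"]
    n0 = pd.to_numeric(n0.reindex(barcodes, fill_value=0)).to_numpy(float)
    n_after = pd.to_numeric(n_after.reindex(barcodes, fill_value=0)).to_numpy(float)

    r_raw = np.log2((n_after + 1.0) / (n0 + 1.0))
    v_s = _LOG2_SQ * (1.0 / (1.0 + n_after) + 1.0 / (1.0 + n0))
    w_s = 1.0 / v_s

    frac = pool["gene_fraction"].to_numpy(float)
    used = (
        (frac >= CENTRAL_WINDOW[0])
        & (frac <= CENTRAL_WINDOW[1])
        & (n0 >= MIN_TIME0_READS)
    )
    if not used.any():
        raise EmptyAssayError("no strain passed the central-insertion/Time0-count filter")

    out = pd.DataFrame(
        {
            "barcode": barcodes.to_numpy(),
            "locus_tag": pool["locus_tag"].to_numpy(),
            "n0": n0,
            "n_after": n_after,
            "r_raw": r_raw,
            "w_s": w_s,
            "used": used,
        }
    )

    # preliminary (unnormalized) gene fitness -> per-sample median shift
    u = out[out["used"]]
    prelim = u.groupby("locus_tag").apply(
        lambda d: np.average(d["r_raw"], weights=d["w_s"]), include_groups=False
    )
    m = float(np.median(prelim.to_numpy()))
    out["f_s"] = out["r_raw"] - m
    return out


def gene_fitness(strains: pd.DataFrame, total0: float, total_after: float) -> pd.DataFrame:
    """Aggregate used strains into per-gene fitness records.

    ``total0``/``total_after`` are the total read counts of the two
    samples; read summaries are reported in counts per million so that
    the before/after direction check downstream is depth-free. Genes with
    no used strain are absent from the output (no insertion data).

    Returns a DataFrame indexed by ``locus_tag`` with columns ``f``,
    ``t``, ``V_g``, ``n_strains``, ``reads_before``, ``reads_after``.
    """
    u = strains[strains["used"]]
    if u.empty:
        raise EmptyAssayError("no used strains to aggregate")

    rows = {}
    for gene, d in u.groupby("locus_tag"):
        f_s = d["f_s"].to_numpy(float)
        w = d["w_s"].to_numpy(float)
        k = len(f_s)
        f_g = float(np.average(f_s, weights=w))
        v_count = 1.0 / float(w.sum())
        if k == 1:
            v_between = v_count
        else:
            v_between = float(np.average((f_s - f_g) ** 2, weights=w)) / (k - 1)
        v_g = max(v_count, v_between)
        rows[gene] = {
            "f": f_g,
            "t": f_g / math.sqrt(v_g + SIGMA0**2),
            "V_g": v_g,
            "n_strains": k,
            "reads_before": float(d["n0"].sum()) / total0 * 1e6,
            "reads_after": float(d["n_after"].sum()) / total_after * 1e6,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "locus_tag"
    out["n_strains"] = out["n_strains"].astype(int)
    return out.sort_index()


def t_statistic(f_g: float, v_g: float, sigma0: float = SIGMA0) -> float:
    """Moderated t: fitness over its floored standard error."""
    return f_g / math.sqrt(v_g + sigma0**2)


def average_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-replicate gene tables into one record per gene.

    The combined fitness is the arithmetic mean of the per-replicate
    fitness values; the combined t divides it by the standard error of
    that mean, sum_r(V_r + sigma0^2) / R^2 under independence. Read
    summaries are summed. A gene enters with whichever replicates
    measured it (R is per-gene).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    if len(replicates) == 1:
        out = replicates[0].copy()
        out["n_replicates"] = 1
        out["f_reps"] = [(v,) for v in out["f"]]
        return out

    stacked = pd.concat(replicates, keys=range(len(replicates)), names=["rep"])
    rows = {}
    for gene, d in stacked.groupby(level="locus_tag"):
        f_vals = d["f"].to_numpy(float)
        v_vals = d["V_g"].to_numpy(float)
        r = len(f_vals)
        f_bar = float(f_vals.mean())
        se2 = float((v_vals + SIGMA0**2).sum()) / r**2
        rows[gene] = {
            "f": f_bar,
            "t": f_bar / math.sqrt(se2),
            "V_g": float(v_vals.sum()) / r**2,  # counting part only
            "n_strains": int(d["n_strains"].max()),
            "reads_before": float(d["reads_before"].sum()),
            "reads_after": float(d["reads_after"].sum()),
            "n_replicates": r,
            "f_reps": tuple(float(x) for x in f_vals),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "locus_tag"
    for col in ("n_strains", "n_replicates"):
        out[col] = out[col].astype(int)
    return out.sort_index()


def fit_assay(
    pool: pd.DataFrame,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Run the full estimator over every treated sample in an experiment.

    Parameters
    ----------
    pool
        Mutant pool table (``barcode``, ``locus_tag``, ``gene_fraction``).
    counts
        Barcode x sample count matrix (index barcodes, one column per
        sample).
    samples
        Sample sheet with columns ``sample``, ``condition`` (Ctrl/Max/
        Dil), ``replicate``, ``is_time0``, ``tailocin_source``,
        ``time0_sample`` (the paired Time0 sample for treated rows).

    Returns
    -------
    Long-format gene table with one row per (condition, tailocin_source,
    locus_tag), replicate-averaged, columns as in
    :func:`average_replicates` plus ``condition`` and
    ``tailocin_source``.
    """
    samples = samples.copy()
    samples["is_time0"] = samples["is_time0"].astype(bool)
    treated = samples[~samples["is_time0"]]
    time0_names = set(samples[samples["is_time0"]]["sample"])

    per_condition: dict[tuple[str, str], list[pd.DataFrame]] = {}
    for _, row in treated.iterrows():
        t0 = row.get("time0_sample")
        if not isinstance(t0, str) or t0 not in time0_names or t0 not in counts:
            raise PairingError(f"treated sample {row['sample']!r} has no valid Time0 pairing")
        if row["sample"] not in counts:
            raise PairingError(f"sample {row['sample']!r} missing from the count matrix")
        strains = strain_fitness(pool, counts[t0], counts[row["sample"]])
        genes = gene_fitness(
            strains,
            total0=float(counts[t0].sum()),
            total_after=float(counts[row["sample"]].sum()),
        )
        key = (str(row["condition"]), str(row.get("tailocin_source", "")))
        per_condition.setdefault(key, []).append(genes)

    blocks = []
    for (condition, source), reps in sorted(per_condition.items()):
        avg = average_replicates(reps)
        avg = avg.reset_index()
        avg.insert(1, "condition", condition)
        avg.insert(2, "tailocin_source", source)
        blocks.append(avg)
    if not blocks:
        raise PairingError("no treated samples found in the sample sheet")
    return pd.concat(blocks, ignore_index=True)
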