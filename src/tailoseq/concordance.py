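"""Sensitivity matrices from spot tests and OSA-phenotype concordance.

A spot test deposits a tailocin sample on a lawn of the target strain;
a zone of inhibition marks the interaction as sensitive. Replicates are
collapsed by unanimity: all-agree gives the call, any disagreement gives
"ambiguous". The concordance statistic C asks how often clades of
strains with similar OSA clusters share an identical sensitivity
vector: C = (# clusters of size >= 2 whose members agree) / (# clusters
of size >= 2), with ambiguous entries excluded column-wise. A
permutation test shuffles strain rows to give C a null distribution.

C and its permutation null are this package's formalization of a
comparison usually made by eye on an annotated tree; outputs label them
as such.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import TailoseqError

__all__ = [
    "build_matrix",
    "self_kill_count",
    "pattern_homogeneity",
    "permutation_test",
]

SENSITIVE, RESISTANT, AMBIGUOUS = "sensitive", "resistant", "ambiguous"


def build_matrix(records: pd.DataFrame, producers: dict[str, str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Collapse replicate spot records into a sensitivity matrix.

    ``records`` columns: ``target``, ``tailocin``, ``replicate``,
    ``inhibition`` (boolean zone-of-inhibition flag). Unanimous
    replicates give ``sensitive``/``resistant``; discordant replicates
    give ``ambiguous``. Returns the strain x tailocin matrix plus a
    summary dict with the sensitive-interaction count and, when
    ``producers`` maps tailocin sample -> producing strain, the
    self-kill count.
    """
    dup = records.duplicated(["target", "tailocin", "replicate"])
    if dup.any():
        row = records[dup].iloc[0]
        raise TailoseqError(
            f"duplicate spot record: target={row['target']!r} tailocin={row['tailocin']!r} "
            f"replicate={row['replicate']!r}"
        )

    def consensus(flags: pd.Series) -> str:
        vals = set(bool(v) for v in flags)
        if vals == {True}:
            return SENSITIVE
        if vals == {False}:
            return RESISTANT
        return AMBIGUOUS

    matrix = (
        records.groupby(["target", "tailocin"])["inhibition"].apply(consensus).unstack("tailocin")
    )
    matrix.index.name = "strain"
    summary = {
        "n_sensitive": int((matrix == SENSITIVE).to_numpy().sum()),
        "n_interactions": int(matrix.size),
        "n_ambiguous": int((matrix == AMBIGUOUS).to_numpy().sum()),
    }
    if producers:
        summary["self_kill_count"] = self_kill_count(matrix, producers)
    return matrix, summary


def self_kill_count(matrix: pd.DataFrame, producers: dict[str, str]) -> int:
    """How many tailocin samples are lethal to their own producing strain."""
    count = 0
    for tailocin, producer in producers.items():
        if producer in matrix.index and tailocin in matrix.columns:
            count += matrix.loc[producer, tailocin] == SENSITIVE
    return int(count)


def _encode(matrix: pd.DataFrame) -> np.ndarray:
    codes = np.full(matrix.shape, -1, dtype=np.int8)
    codes[(matrix == SENSITIVE).to_numpy()] = 1
    codes[(matrix == RESISTANT).to_numpy()] = 0
    return codes


def _homogeneity(codes: np.ndarray, cluster_rows: list[np.ndarray]) -> tuple[float, list[bool]]:
    flags = []
    for rows in cluster_rows:
        block = codes[rows]
        ok = True
        for col in range(block.shape[1]):
            vals = block[:, col]
            vals = vals[vals >= 0]  # drop ambiguous pairwise
            if vals.size and not (vals == vals[0]).all():
                ok = False
                break
        flags.append(ok)
    if not flags:
        raise TailoseqError("no cluster of size >= 2; homogeneity undefined")
    return sum(flags) / len(flags), flags


def pattern_homogeneity(
    matrix: pd.DataFrame, partition: dict[str, int]
) -> tuple[float, pd.DataFrame]:
    """Fraction of multi-member clusters with an identical sensitivity vector.

    ``partition`` maps every matrix row (strain) to a cluster id.
    Ambiguous entries are ignored when comparing members. Returns
    ``(C, report)`` with a per-cluster report (size, homogeneous flag,
    members).
    """
    missing = set(matrix.index) - set(partition)
    extra = set(partition) - set(matrix.index)
    if missing or extra:
        raise TailoseqError(
            f"partition/matrix mismatch: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
        )
    codes = _encode(matrix)
    row_of = {s: i for i, s in enumerate(matrix.index)}
    clusters: dict[int, list[str]] = {}
    for strain, cid in partition.items():
        clusters.setdefault(cid, []).append(strain)

    eligible = {cid: members for cid, members in clusters.items() if len(members) >= 2}
    cluster_rows = [np.array([row_of[s] for s in members]) for members in eligible.values()]
    c_stat, flags = _homogeneity(codes, cluster_rows)

    report = pd.DataFrame(
        {
            "cluster": list(eligible),
            "size": [len(m) for m in eligible.values()],
            "homogeneous": flags,
            "members": [",".join(sorted(m)) for m in eligible.values()],
        }
    )
    return c_stat, report


def permutation_test(
    matrix: pd.DataFrame,
    partition: dict[str, int],
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for the homogeneity statistic C.

    Strain rows are shuffled uniformly relative to the fixed partition;
    p = (1 + #{C* >= C_obs}) / (M + 1) (add-one, so p is never 0).
    Returns ``(C_obs, p)``.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    c_obs, _ = pattern_homogeneity(matrix, partition)
    codes = _encode(matrix)
    row_of = {s: i for i, s in enumerate(matrix.index)}
    clusters: dict[int, list[str]] = {}
    for strain, cid in partition.items():
        clusters.setdefault(cid, []).append(strain)
    cluster_rows = [
        np.array([row_of[s] for s in members])
        for members in clusters.values()
        if len(members) >= 2
    ]
    rng = np.random.default_rng(seed)
    n = codes.shape[0]
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        c_star, _ = _homogeneity(codes[perm], cluster_rows)
        if c_star >= c_obs:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return c_obs, p
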