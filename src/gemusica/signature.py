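"""Unsupervised high-variance signature selection.

The melodies are generated not from whole arrays but from a "prefiltered"
list of the probe sets with the highest cross-sample variance — for an
HG-U133A-sized matrix (22,283 probe sets) the conventional fraction is 5%,
giving N = 1114. The signature is selected once on reference samples and
then re-applied to combined reference+query matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrix import ExpressionMatrix, IdentifierError

__all__ = ["SignatureSet", "select_high_variance", "apply_signature",
           "read_signature", "write_signature"]


@dataclass(frozen=True)
class SignatureSet:
    """Ordered probe-set signature: ids by descending variance.

    ``source_fraction`` records the fraction of the source matrix the
    signature was cut at (1.0 when selected by absolute count).
    """

    probe_ids: tuple[str, ...]
    variances: tuple[float, ...]
    source_fraction: float = 1.0

    def __post_init__(self) -> None:
        if len(self.probe_ids) != len(self.variances):
            raise ValueError("probe_ids and variances length mismatch")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise IdentifierError("signature contains duplicate probe ids")
        v = np.asarray(self.variances, float)
        if v.size and (np.any(v < 0) or np.any(np.diff(v) > 1e-12)):
            raise ValueError("variances must be non-negative and non-increasing")
        if not (0 < self.source_fraction <= 1):
            raise ValueError("source_fraction must lie in (0, 1]")

    @property
    def n(self) -> int:
        return len(self.probe_ids)

    def __len__(self) -> int:
        return self.n


def select_high_variance(
    m: ExpressionMatrix,
    *,
    fraction: float | None = None,
    n: int | None = None,
    ddof: int = 1,
) -> SignatureSet:
    """Select the top-variance probe sets of a normalized log2 matrix.

    Exactly one of ``fraction`` (count = floor(fraction * n_probes)) or ``n``
    must be given. Variance uses the unbiased estimator by default
    (``ddof=1``). Ordering is by descending variance with ties broken by
    probe id (ascending lexicographic), so selection is deterministic and
    independent of input row order.
    """
    if (fraction is None) == (n is None):
        raise ValueError("give exactly one of fraction or n")
    if m.n_samples < 2:
        raise ValueError("variance selection needs at least 2 samples")
    if fraction is not None:
        if not (0 < fraction <= 1):
            raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
        n = int(np.floor(fraction * m.n_probes))
        if n == 0:
            raise ValueError(f"fraction {fraction} selects zero probes")
        src_frac = fraction
    else:
        assert n is not None
        if not (1 <= n <= m.n_probes):
            raise ValueError(f"n must lie in [1, {m.n_probes}], got {n}")
        src_frac = 1.0
    variances = m.values.var(axis=1, ddof=ddof)
    order = sorted(range(m.n_probes), key=lambda i: (-variances[i], m.probe_ids[i]))
    top = order[:n]
    return SignatureSet(
        tuple(m.probe_ids[i] for i in top),
        tuple(float(variances[i]) for i in top),
        source_fraction=src_frac,
    )


def apply_signature(m: ExpressionMatrix, s: SignatureSet) -> ExpressionMatrix:
    """Restrict ``m`` to the signature probes, rows reordered to signature order."""
    index = {pid: i for i, pid in enumerate(m.probe_ids)}
    missing = [pid for pid in s.probe_ids if pid not in index]
    if missing:
        raise IdentifierError(
            f"{len(missing)} signature probe(s) absent from matrix: {missing[:5]}"
        )
    rows = [index[pid] for pid in s.probe_ids]
    return ExpressionMatrix(s.probe_ids, m.sample_ids, m.values[rows], m.scale_tag)


def write_signature(s: SignatureSet, path: str | Path) -> None:
    """Two-column TSV (probe_id, variance); row order is the signature order."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("probe_id\tvariance\n")
        for pid, v in zip(s.probe_ids, s.variances):
            fh.write(f"{pid}\t{v!r}\n")


def read_signature(path: str | Path) -> SignatureSet:
    probe_ids: list[str] = []
    variances: list[float] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("probe_id\t"):
            raise ValueError(f"{path}: not a signature file")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, var = line.split("\t")
            probe_ids.append(pid)
            variances.append(float(var))
    return SignatureSet(tuple(probe_ids), tuple(variances))
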