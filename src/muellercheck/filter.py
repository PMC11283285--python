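"""Pixel-wise realizability filtering of Mueller-matrix images.

A Mueller image is a rows x cols grid of 4x4 Mueller matrices, one per
camera pixel.  ``filter_image`` classifies every pixel independently with a
chosen realizability test and returns a boolean mask plus summary counts of
nonphysical pixels.  Work is split into blocks of whole rows; each pixel is
written exactly once, so the mask is bit-identical for any worker count or
chunk size.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .checks import Tolerance

__all__ = [
    "MuellerImage",
    "FilterConfig",
    "RealizabilityMask",
    "filter_image",
    "compare_methods",
    "benchmark",
]

log = logging.getLogger("muellercheck")

INVALID_POLICIES = ("count_as_nonphysical", "exclude")


@dataclass
class MuellerImage:
    """rows x cols grid of Mueller matrices.

    ``data`` has shape (rows, cols, 4, 4); pixels with non-finite entries
    are flagged in ``invalid_mask`` (and their data replaced by zeros so
    downstream arithmetic stays finite).
    """

    data: np.ndarray
    invalid_mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[2:] != (4, 4):
            raise ValueError(
                f"image data must have shape (rows, cols, 4, 4), got {self.data.shape}"
            )
        if self.rows == 0 or self.cols == 0:
            raise ValueError("empty image")
        self.invalid_mask = np.asarray(self.invalid_mask, dtype=bool)
        if self.invalid_mask.shape != self.data.shape[:2]:
            raise ValueError("invalid_mask shape does not match image")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_array(cls, data: np.ndarray) -> "MuellerImage":
        """Build an image from raw per-pixel matrices, flagging non-finite pixels."""
        data = np.asarray(data, dtype=np.float64)
        finite = np.isfinite(data).all(axis=(2, 3))
        invalid = ~finite
        if invalid.any():
            n = int(invalid.sum())
            log.warning("image contains %d pixel(s) with non-finite entries", n)
            data = data.copy()
            data[invalid] = 0.0
        return cls(data=data, invalid_mask=invalid)


@dataclass(frozen=True)
class FilterConfig:
    """Configuration of a pixel-wise filtering run.

    ``criterion=None`` selects the method default (semidefinite for the
    eigenvalue and CP tests, strict definiteness for Cholesky/Sylvester).
    ``workers`` and ``chunk_rows`` affect speed only, never the result.
    """

    method: str = "cp_pauli"
    tolerance: Tolerance = field(default_factory=Tolerance)
    criterion: Optional[str] = None
    workers: int = 1
    chunk_rows: int = 64
    invalid_policy: str = "count_as_nonphysical"

    def __post_init__(self):
        if self.method not in _kernels.METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; valid methods: {_kernels.METHODS}"
            )
        if self.workers < 1 or self.chunk_rows < 1:
            raise ValueError("workers and chunk_rows must be >= 1")
        if self.invalid_policy not in INVALID_POLICIES:
            raise ValueError(
                f"unknown invalid_policy {self.invalid_policy!r}; "
                f"valid: {INVALID_POLICIES}"
            )

    @property
    def effective_criterion(self) -> str:
        return self.criterion or _kernels.DEFAULT_CRITERION[self.method]


@dataclass
class RealizabilityMask:
    """Per-pixel physical/nonphysical verdicts with summary counts.

    ``physical[r, c]`` is True where the pixel's coherency matrix passed the
    test.  Invalid (non-finite) pixels are counted as nonphysical or
    excluded per the filter's ``invalid_policy``; ``n_invalid`` reports them
    separately either way.
    """

    physical: np.ndarray
    method: str
    criterion: str
    tolerance: Tolerance
    n_invalid: int = 0
    invalid_policy: str = "count_as_nonphysical"

    @property
    def rows(self) -> int:
        return self.physical.shape[0]

    @property
    def cols(self) -> int:
        return self.physical.shape[1]

    @property
    def n_total(self) -> int:
        return int(self.physical.size)

    @property
    def n_nonphysical(self) -> int:
        n = int((~self.physical).sum())
        if self.invalid_policy == "exclude":
            n -= self.n_invalid
        return n

    @property
    def n_physical(self) -> int:
        return int(self.physical.sum())

    @property
    def fraction_nonphysical(self) -> float:
        denom = self.n_total
        if self.invalid_policy == "exclude":
            denom -= self.n_invalid
        return self.n_nonphysical / denom if denom else 0.0

    def summary(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "method": self.method,
            "criterion": self.criterion,
            "abs_tol": self.tolerance.abs_tol,
            "rel_tol": self.tolerance.rel_tol,
            "invalid_policy": self.invalid_policy,
            "n_total": self.n_total,
            "n_invalid": self.n_invalid,
            "n_nonphysical": self.n_nonphysical,
            "fraction_nonphysical": self.fraction_nonphysical,
        }


def _row_chunks(rows: int, chunk_rows: int):
    return [(r0, min(r0 + chunk_rows, rows)) for r0 in range(0, rows, chunk_rows)]


def filter_image(
    img: MuellerImage, cfg: FilterConfig = FilterConfig(), return_witness: bool = False
):
    """Classify every pixel of a Mueller image with one realizability test.

    Pixels are processed in blocks of whole rows, optionally across a thread
    pool; each block writes a disjoint slice of the output, so the mask is
    bit-identical regardless of ``workers``/``chunk_rows``.

    Returns a :class:`RealizabilityMask` (and, with ``return_witness=True``,
    the per-pixel witness array).
    """
    criterion = cfg.effective_criterion
    physical = np.empty((img.rows, img.cols), dtype=bool)
    witness = np.empty((img.rows, img.cols), dtype=np.float64)
    chunks = _row_chunks(img.rows, cfg.chunk_rows)

    def run(span):
        r0, r1 = span
        block = img.data[r0:r1].reshape(-1, 4, 4)
        ok, wit = _kernels.classify_batch(block, cfg.method, cfg.tolerance, criterion)
        physical[r0:r1] = ok.reshape(r1 - r0, img.cols)
        witness[r0:r1] = wit.reshape(r1 - r0, img.cols)
        log.debug("chunk rows [%d, %d): %d nonphysical", r0, r1, int((~ok).sum()))

    t0 = time.perf_counter()
    if cfg.workers == 1 or len(chunks) == 1:
        for span in chunks:
            run(span)
    else:
        with ThreadPoolExecutor(max_workers=cfg.workers) as ex:
            list(ex.map(run, chunks))
    elapsed = time.perf_counter() - t0

    n_invalid = int(img.invalid_mask.sum())
    if n_invalid:
        # invalid pixels never count as physical, whatever the kernel said
        physical[img.invalid_mask] = False
        witness[img.invalid_mask] = np.nan
        log.warning(
            "%d invalid pixel(s) handled with policy %r", n_invalid, cfg.invalid_policy
        )
    mask = RealizabilityMask(
        physical=physical,
        method=cfg.method,
        criterion=criterion,
        tolerance=cfg.tolerance,
        n_invalid=n_invalid,
        invalid_policy=cfg.invalid_policy,
    )
    log.info(
        "filter %s/%s: %d of %d pixels nonphysical (%.4f%%) in %.3f s",
        cfg.method, criterion, mask.n_nonphysical, mask.n_total,
        100.0 * mask.fraction_nonphysical, elapsed,
    )
    if return_witness:
        return mask, witness
    return mask


def compare_methods(
    img: MuellerImage,
    methods: Sequence[str],
    cfg: FilterConfig = FilterConfig(),
) -> dict:
    """Run several realizability tests on the same image and compare masks.

    Disagreeing pixels are split into *boundary* disagreements -- where the
    smallest eigenvalue is within 10x the effective threshold of zero, so
    methods may legitimately differ -- and *non-boundary* ones, which
    indicate a genuine numerical discrepancy.

    Returns a dict with per-method masks and the agreement report.
    """
    methods = list(methods)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    masks = {}
    for meth in methods:
        masks[meth] = filter_image(img, replace(cfg, method=meth, criterion=None))

    # canonical per-pixel margin: smallest eigenvalue of H
    from .core import coherency_from_mueller

    h = coherency_from_mueller(img.data.reshape(-1, 4, 4))
    lmin = np.linalg.eigvalsh(h)[..., 0].reshape(img.rows, img.cols)
    tau = np.maximum(
        cfg.tolerance.abs_tol,
        cfg.tolerance.rel_tol * np.abs(img.data[..., 0, 0]),
    )
    boundary = np.abs(lmin) <= 10.0 * tau

    stack = np.stack([masks[m].physical for m in methods])
    disagree = stack.any(axis=0) & ~stack.all(axis=0)
    report = {
        "methods": methods,
        "n_disagree": int(disagree.sum()),
        "n_boundary_disagree": int((disagree & boundary).sum()),
        "n_nonboundary_disagree": int((disagree & ~boundary).sum()),
        "disagree_pixels": np.argwhere(disagree),
        "nonboundary_pixels": np.argwhere(disagree & ~boundary),
    }
    log.info(
        "compare %s: %d disagreements (%d at PSD boundary, %d elsewhere)",
        methods, report["n_disagree"], report["n_boundary_disagree"],
        report["n_nonboundary_disagree"],
    )
    return {"masks": masks, "report": report}


def benchmark(
    img: MuellerImage,
    methods: Sequence[str] = _kernels.METHODS,
    workers_list: Sequence[int] = (1,),
    repeats: int = 3,
    cfg: FilterConfig = FilterConfig(),
):
    """Wall-clock timing of each method at each worker count.

    Returns a pandas DataFrame with mean and standard deviation of the
    elapsed time over ``repeats`` runs per (method, workers) cell.  Timings
    are hardware-dependent observations, not assertions; the expected (not
    guaranteed) ranking on large images is the Pauli-trace CP test fastest
    and the eigenvalue test slowest.
    """
    import pandas as pd

    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    records = []
    for meth in methods:
        for w in workers_list:
            run_cfg = replace(cfg, method=meth, criterion=None, workers=int(w))
            times = []
            for _ in range(repeats):
                t0 = time.perf_counter()
                filter_image(img, run_cfg)
                times.append(time.perf_counter() - t0)
            records.append(
                {
                    "method": meth,
                    "workers": int(w),
                    "mean_s": float(np.mean(times)),
                    "sd_s": float(np.std(times)),
                    "repeats": repeats,
                }
            )
    table = pd.DataFrame.from_records(records)
    order = (
        table[table.workers == min(workers_list)]
        .sort_values("mean_s")["method"]
        .tolist()
    )
    log.info("benchmark ranking (fastest first): %s", order)
    return table
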