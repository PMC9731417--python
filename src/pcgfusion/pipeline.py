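"""End-to-end glue: EMD reconstruction and feature extraction as sklearn
transformers, plus batch helpers that turn labelled recordings into a
FeatureMatrix ready for ranking and classification.

Signals are variable-length 1-D arrays, so both transformers accept and
return Python lists of arrays rather than a rectangular X; the feature
extractor's output is the rectangular n-by-p feature table.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import selection as sel
from .emd import SiftConfig, decompose
from .errors import SegmentationError, SelectionError
from .features import FEATURE_NAMES, extract_all
from .io import PCGRecord, PIPELINE_FS
from .ranking import FeatureMatrix
from .segmentation import segment

__all__ = ["EMDReconstructor", "PCGFeatureExtractor",
           "process_record", "build_feature_matrix", "RECONSTRUCTION_METHODS"]

RECONSTRUCTION_METHODS = ("none", "corr_rmse", "hd", "adaptive_hd")


def _samples(x) -> np.ndarray:
    return x.samples if isinstance(x, PCGRecord) else np.asarray(x, dtype=float)


class EMDReconstructor(BaseEstimator, TransformerMixin):
    """Decompose each signal by EMD, screen IMFs, and sum the kept layers.

    ``method`` is one of {none, corr_rmse, hd, adaptive_hd}; ``none`` passes
    signals through untouched.  Selection reports of the latest transform are
    kept on ``reports_`` for audit.
    """

    def __init__(self, method: str = "adaptive_hd", fs: float = PIPELINE_FS,
                 sd_threshold: float = 0.2, max_sifts: int = 50,
                 max_imfs: int = 15, hd_space: str = "time_amplitude_2d",
                 hd_max_points: int = 2000):
        self.method = method
        self.fs = fs
        self.sd_threshold = sd_threshold
        self.max_sifts = max_sifts
        self.max_imfs = max_imfs
        self.hd_space = hd_space
        self.hd_max_points = hd_max_points

    def fit(self, X=None, y=None):
        if self.method not in RECONSTRUCTION_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        return self

    def transform_one(self, x) -> tuple[np.ndarray, "sel.SelectionReport | None"]:
        x = _samples(x)
        if self.method == "none":
            return x, None
        cfg = SiftConfig(sd_threshold=self.sd_threshold,
                         max_sifts=self.max_sifts, max_imfs=self.max_imfs)
        imfs = decompose(x, cfg)
        if len(imfs) < 2:
            warnings.warn("too few IMFs; passing signal through", stacklevel=2)
            return x, None
        try:
            report = sel.select(x, imfs, self.method, fs=self.fs,
                                hd_space=self.hd_space,
                                hd_max_points=self.hd_max_points)
        except SelectionError:
            warnings.warn("selection failed; passing signal through", stacklevel=2)
            return x, None
        return sel.reconstruct(imfs, report.selected), report

    def transform(self, X):
        self.fit()
        out, reports = [], []
        for x in X:
            y, rep = self.transform_one(x)
            out.append(y)
            reports.append(rep)
        self.reports_ = reports
        return out


class PCGFeatureExtractor(BaseEstimator, TransformerMixin):
    """Extract the fused feature vector from each signal.

    Reserve times come from envelope segmentation of the signal itself; when
    segmentation fails they are NaN (FeatureMatrix imputes column medians).
    """

    def __init__(self, fs: float = PIPELINE_FS, include_reserve: bool = True):
        self.fs = fs
        self.include_reserve = include_reserve

    def fit(self, X=None, y=None):
        self.feature_names_ = list(FEATURE_NAMES if self.include_reserve
                                   else FEATURE_NAMES[4:])
        return self

    def transform_one(self, x) -> dict[str, float]:
        x = _samples(x)
        seg = None
        if self.include_reserve:
            try:
                seg = segment(x, self.fs)
                if len(seg) < 2:
                    seg = None
            except SegmentationError:
                seg = None
        return extract_all(x, self.fs, seg, self.include_reserve)

    def transform(self, X) -> np.ndarray:
        self.fit()
        rows = [self.transform_one(x) for x in X]
        return np.array([[r[n] for n in self.feature_names_] for r in rows])


def process_record(record, method: str = "adaptive_hd",
                   include_reserve: bool = True, fs: float | None = None,
                   **emd_kw):
    """Reconstruct one record and extract its features.

    Returns (feature dict, selection report).  Segmentation for the reserve
    times runs on the reconstructed signal (already denoised).
    """
    x = _samples(record)
    fs = fs or (record.fs if isinstance(record, PCGRecord) else PIPELINE_FS)
    recon = EMDReconstructor(method=method, fs=fs, **emd_kw)
    y, report = recon.transform_one(x)
    ext = PCGFeatureExtractor(fs=fs, include_reserve=include_reserve)
    return ext.fit().transform_one(y), report


def build_feature_matrix(records, method: str = "adaptive_hd",
                         include_reserve: bool = True,
                         **emd_kw) -> FeatureMatrix:
    """Run the full preprocessing + feature pipeline over labelled records."""
    rows, labels = [], []
    for rec in records:
        feats, _ = process_record(rec, method=method,
                                  include_reserve=include_reserve, **emd_kw)
        rows.append(feats)
        labels.append(rec.label if isinstance(rec, PCGRecord) else "")
    names = list(rows[0].keys())
    values = np.array([[r[n] for n in names] for r in rows])
    return FeatureMatrix(values=values, labels=np.asarray(labels),
                         feature_names=names)
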