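"""Single-cell Raman D₂O-labeling pipeline.

Cells growing in heavy water build deuterium into C-D bonds, which scatter
in an otherwise silent spectral region (2040–2300 cm⁻¹) red-shifted from the
C-H stretch (2800–3100 cm⁻¹).  The fraction A(C-D)/[A(C-D)+A(C-H)] — the
C-D ratio — is therefore a per-cell proxy for metabolic activity.

Preprocessing follows the fixed order despike → calibrate → baseline →
normalize.  Wavenumber and intensity calibration are pass-through hooks:
they require physical standard spectra (4-acetamidophenol, SRM2242), so
synthetic and pre-calibrated data skip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "RamanSpectrum",
    "CDRatio",
    "despike",
    "als_baseline",
    "vector_normalize",
    "cd_ratio",
    "RamanPipeline",
    "train_label_classifier",
    "LabelClassifier",
    "CD_WINDOW",
    "CH_WINDOW",
]

#: Default integration windows in cm⁻¹ for the C-D and C-H stretch bands.
CD_WINDOW = (2040.0, 2300.0)
CH_WINDOW = (2800.0, 3100.0)


@dataclass(frozen=True)
class RamanSpectrum:
    """One spectrum on a strictly increasing wavenumber axis (cm⁻¹)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wn.shape != inten.shape or wn.ndim != 1:
            raise ValueError("axes must be 1-D and of equal length")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", inten)

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass(frozen=True)
class CDRatio:
    """C-D ratio A(C-D)/[A(C-D)+A(C-H)] with the areas it derives from."""

    value: float
    a_cd: float
    a_ch: float
    cd_window: tuple[float, float]
    ch_window: tuple[float, float]


def despike(
    spectrum: RamanSpectrum, window: int = 7, z_threshold: float = 8.0
) -> RamanSpectrum:
    """Replace cosmic-spike points by the local median.

    A point deviating from its running median by more than `z_threshold`
    robust standard deviations (1.4826·MAD of the residuals) is a spike.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    y = spectrum.intensities
    from scipy.ndimage import median_filter

    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    if sigma <= 0:
        sigma = np.std(resid) or 1.0
    out = y.copy()
    spikes = np.abs(resid) > z_threshold * sigma
    out[spikes] = med[spikes]
    return spectrum.with_intensities(out)


def als_baseline(
    spectrum: RamanSpectrum,
    smoothness: float = 1e7,
    asymmetry: float = 0.01,
    iterations: int = 10,
    tol: float = 1e-6,
    presmooth: int = 21,
) -> tuple[RamanSpectrum, RamanSpectrum]:
    """Asymmetric least-squares baseline estimation.

    Iteratively reweighted penalized least squares: the baseline minimizes
    ``Σ wᵢ(yᵢ − zᵢ)² + λ Σ(Δ²z)²`` with weights `asymmetry` for points above
    the current baseline and ``1 − asymmetry`` below, so the fit hugs the
    lower envelope (fluorescence background) and ignores peaks.

    The asymmetric weights are computed against a Savitzky-Golay-smoothed
    copy of the spectrum (`presmooth` window, cubic; 0 disables); otherwise
    the fitted baseline tracks the lower envelope of the *noise* rather than
    the background, leaving a positive offset in the corrected spectrum that
    biases integrated band areas.  The smoothed copy is used only to place
    the baseline; the correction is applied to the original intensities.

    Returns ``(baseline, corrected)``; a ``converged`` flag lands in the
    corrected spectrum's metadata.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if not 0 < asymmetry < 1:
        raise ValueError("asymmetry must lie in (0, 1)")
    y_raw = spectrum.intensities
    n = len(y_raw)
    if presmooth and presmooth >= 5 and n > presmooth:
        from scipy.signal import savgol_filter

        y = savgol_filter(y_raw, presmooth, 3)
    else:
        y = y_raw
    D = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    penalty = smoothness * (D @ D.T)
    w = np.ones(n)
    z = y.copy()
    converged = False
    for _ in range(iterations):
        W = sparse.diags(w)
        z_new = spsolve((W + penalty).tocsc(), w * y)
        if np.max(np.abs(z_new - z)) <= tol * max(np.max(np.abs(y)), 1.0):
            z = z_new
            converged = True
            break
        z = z_new
        w = np.where(y > z, asymmetry, 1.0 - asymmetry)
    baseline = spectrum.with_intensities(z)
    corrected = RamanSpectrum(
        spectrum.wavenumbers,
        y_raw - z,
        metadata={**spectrum.metadata, "baseline_converged": converged},
    )
    return baseline, corrected


def vector_normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm == 0:
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return spectrum.with_intensities(spectrum.intensities / norm)


def cd_ratio(
    spectrum: RamanSpectrum,
    cd_window: tuple[float, float] = CD_WINDOW,
    ch_window: tuple[float, float] = CH_WINDOW,
) -> CDRatio:
    """Integrate the C-D and C-H bands and form their ratio.

    Trapezoidal integration on the baseline-corrected spectrum; negative
    intensities are floored at zero before integrating.  Scale-invariant, so
    it does not matter whether the input was vector-normalized.
    """
    areas = []
    for lo, hi in (cd_window, ch_window):
        if lo < spectrum.wavenumbers[0] or hi > spectrum.wavenumbers[-1]:
            raise ValueError(
                f"window {lo}-{hi} cm^-1 outside spectral axis "
                f"{spectrum.wavenumbers[0]:.0f}-{spectrum.wavenumbers[-1]:.0f}"
            )
        mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
        y = np.clip(spectrum.intensities[mask], 0.0, None)
        areas.append(float(np.trapezoid(y, spectrum.wavenumbers[mask])))
    a_cd, a_ch = areas
    total = a_cd + a_ch
    value = a_cd / total if total > 0 else 0.0
    return CDRatio(value, a_cd, a_ch, cd_window, ch_window)


_STAGE_ORDER = ("despike", "calibrate", "baseline", "normalize")


class RamanPipeline:
    """Ordered preprocessing pipeline; stage order is fixed.

    Stages must appear in the order despike → calibrate → baseline →
    normalize (any stage may be omitted); an out-of-order build raises.
    ``calibrate`` accepts a user hook and defaults to pass-through.
    """

    def __init__(self, stages: Sequence[tuple[str, dict]] | None = None):
        stages = list(
            stages
            if stages is not None
            else [("despike", {}), ("baseline", {}), ("normalize", {})]
        )
        order = [_STAGE_ORDER.index(name) for name, _ in stages]
        if sorted(order) != order or len(set(order)) != len(order):
            raise ValueError(
                f"stages must follow the order {' -> '.join(_STAGE_ORDER)}"
            )
        self.stages = stages
        self.calibration_hook: Callable[[RamanSpectrum], RamanSpectrum] | None = None

    def __call__(self, spectrum: RamanSpectrum) -> RamanSpectrum:
        s = spectrum
        for name, kwargs in self.stages:
            if name == "despike":
                s = despike(s, **kwargs)
            elif name == "calibrate":
                if self.calibration_hook is not None:
                    s = self.calibration_hook(s)
            elif name == "baseline":
                _, s = als_baseline(s, **kwargs)
            elif name == "normalize":
                s = vector_normalize(s)
        return s


@dataclass
class LabelClassifier:
    """PCA + linear discriminant model for labeled/unlabeled cell calls."""

    mean: np.ndarray
    projection: np.ndarray  # (n_features, n_components)
    lda: object
    classes: tuple
    shrinkage_applied: bool = False

    def transform(self, spectra: Sequence[RamanSpectrum]) -> np.ndarray:
        X = np.stack([s.intensities for s in spectra])
        return (X - self.mean) @ self.projection

    def predict(self, spectra: Sequence[RamanSpectrum]) -> np.ndarray:
        return self.lda.predict(self.transform(spectra))

    def decision_scores(self, spectra: Sequence[RamanSpectrum]) -> np.ndarray:
        return self.lda.decision_function(self.transform(spectra))


def train_label_classifier(
    spectra: Sequence[RamanSpectrum],
    labels: Sequence,
    n_components: int = 5,
) -> LabelClassifier:
    """PCA (default 5 components) followed by linear discriminant analysis.

    Spectra must be preprocessed (despiked, baseline-corrected,
    vector-normalized) and share one wavenumber axis.  If the within-class
    covariance in PC space is singular, LDA is refit with Ledoit-Wolf
    shrinkage and the model is flagged.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(labels)
    classes = tuple(np.unique(labels))
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    thin = [c for c, n in counts.items() if n < n_components + 1]
    if thin:
        raise ValueError(
            f"classes {thin} need at least {n_components + 1} spectra each"
        )
    X = np.stack([s.intensities for s in spectra])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    lda = LinearDiscriminantAnalysis(solver="svd")
    shrinkage = False
    try:
        with np.errstate(all="raise"):
            lda.fit(scores, labels)
    except (FloatingPointError, np.linalg.LinAlgError):
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(scores, labels)
        shrinkage = True
    return LabelClassifier(
        mean=pca.mean_,
        projection=pca.components_.T,
        lda=lda,
        classes=classes,
        shrinkage_applied=shrinkage,
    )


def compare_timepoints(ratios_a: Sequence[float], ratios_b: Sequence[float]):
    """Two-sided Welch's t-test on per-cell C-D ratios of two time points."""
    from scipy import stats

    return stats.ttest_ind(ratios_a, ratios_b, equal_var=False)
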