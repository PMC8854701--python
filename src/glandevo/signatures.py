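"""Mutational-signature exposure fitting against a fixed reference matrix.

A 96-class spectrum is modelled as a multinomial draw from a convex mixture
of known single-base-substitution (SBS) signatures. Exposures are estimated
by maximum likelihood on the simplex with EM-style multiplicative updates
(each iteration provably does not decrease the log-likelihood); uncertainty
comes from a multinomial bootstrap of the spectrum, with percentile
intervals. A signature is called significantly active when the lower end of
its 90% interval exceeds 0.01, mirroring the activity rule used with
posterior intervals in Bayesian refitting tools.

De novo signature extraction is out of scope: spectra from small cohorts
cannot support it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import SpectrumCounts
from .contexts import SBS96_CLASSES

#: Candidate signatures active in >=10% of samples of at least one of the
#: three gynecologic cancers in the COSMIC v3 reference.
DEFAULT_CANDIDATE_SIGNATURES = (
    "SBS1", "SBS2", "SBS3", "SBS5", "SBS10a", "SBS10b",
    "SBS13", "SBS15", "SBS18", "SBS40", "SBS44",
)

SIGNIFICANCE_EXPOSURE_FLOOR = 0.01
DEFAULT_INTERVAL_LEVEL = 0.90


@dataclass
class SignatureMatrix:
    """96 x K matrix of per-class probabilities, one column per signature."""

    names: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (96, len(self.names)):
            raise ValueError("matrix must be 96 x K with K = len(names)")
        if np.any(self.probabilities < 0):
            raise ValueError("negative signature probability")
        sums = self.probabilities.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature column must sum to 1")
        for i in range(len(self.names)):
            for j in range(i + 1, len(self.names)):
                if np.allclose(
                    self.probabilities[:, i], self.probabilities[:, j]
                ):
                    warnings.warn(
                        f"duplicate signature columns {self.names[i]}"
                        f"/{self.names[j]}: exposures are not identifiable"
                    )

    @property
    def k(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probabilities, index=list(SBS96_CLASSES), columns=list(self.names)
        )


def read_signature_tsv(path) -> SignatureMatrix:
    """Read a signature matrix TSV (96 rows x K signature columns).

    The first column must hold the 96 class labels (any order); remaining
    columns are signatures. COSMIC v3-style files load unchanged.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(SBS96_CLASSES) - set(frame.index)
    if missing:
        raise ValueError(f"signature file missing classes: {sorted(missing)[:3]}...")
    frame = frame.loc[list(SBS96_CLASSES)]
    return SignatureMatrix(
        names=tuple(frame.columns), probabilities=frame.to_numpy(dtype=float)
    )


def write_signature_tsv(sigs: SignatureMatrix, path) -> None:
    sigs.to_frame().to_csv(path, sep="\t", index_label="class")


@dataclass
class ExposureEstimate:
    """Fitted signature exposures with bootstrap intervals."""

    names: tuple[str, ...]
    exposures: np.ndarray
    interval_low: np.ndarray
    interval_high: np.ndarray
    significant: np.ndarray
    loglik: float
    n_mutations: int
    level: float = DEFAULT_INTERVAL_LEVEL

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposures,
                "interval_low": self.interval_low,
                "interval_high": self.interval_high,
                "significant": self.significant,
            },
            index=list(self.names),
        )


def _em_fit(
    counts: np.ndarray,
    S: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Multinomial mixture MLE by multiplicative (EM) updates."""
    total = counts.sum()
    k = S.shape[1]
    e = np.full(k, 1.0 / k)
    mask = counts > 0
    x = counts[mask]
    Sm = S[mask, :]
    prev = -np.inf
    for _ in range(max_iter):
        mix = Sm @ e
        np.clip(mix, 1e-300, None, out=mix)
        ll = float(x @ np.log(mix))
        e = e * (Sm.T @ (x / mix)) / total
        e = np.clip(e, 0.0, None)
        e /= e.sum()
        if ll - prev < tol and ll >= prev:
            break
        prev = ll
    mix = np.clip(Sm @ e, 1e-300, None)
    return e, float(x @ np.log(mix))


def fit_exposures(
    spectrum: SpectrumCounts,
    sigs: SignatureMatrix,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = DEFAULT_INTERVAL_LEVEL,
    threshold: float = SIGNIFICANCE_EXPOSURE_FLOOR,
) -> ExposureEstimate:
    """Fit signature exposures to a 96-class spectrum.

    The point estimate maximizes the multinomial likelihood of the counts
    under the mixture sum_k e_k * sig_k on the simplex. ``n_boot``
    multinomial bootstrap replicates of the spectrum give percentile
    intervals at ``level``; a signature is flagged significant when its
    lower bound exceeds ``threshold``.
    """
    counts = np.asarray(spectrum.counts, dtype=float)
    total = counts.sum()
    if total < 1:
        raise ValueError("spectrum must contain at least one mutation")
    S = sigs.probabilities
    e_hat, ll = _em_fit(counts, S)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        p = counts / total
        boots = np.empty((n_boot, sigs.k))
        for b in range(n_boot):
            resampled = rng.multinomial(int(round(total)), p).astype(float)
            boots[b], _ = _em_fit(resampled, S)
        alpha = (1.0 - level) / 2.0
        low = np.quantile(boots, alpha, axis=0)
        high = np.quantile(boots, 1.0 - alpha, axis=0)
        low = np.minimum(low, e_hat)
        high = np.maximum(high, e_hat)
    else:
        low = e_hat.copy()
        high = e_hat.copy()
    return ExposureEstimate(
        names=sigs.names,
        exposures=e_hat,
        interval_low=low,
        interval_high=high,
        significant=low > threshold,
        loglik=ll,
        n_mutations=int(round(total)),
        level=level,
    )
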