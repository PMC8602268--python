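"""Mutational-signature selection and refitting.

A sample's context spectrum is modeled as a nonnegative linear combination
of fixed signature columns S (contexts x signatures):

    minimize || S x - c ||_2   subject to  x >= 0,

solved per clone by Lawson-Hanson non-negative least squares. Candidate
signatures are chosen beforehand by their prevalence in a per-cancer-type
exposure table: a signature is a candidate when it is present (exposure
above a floor, default 0) in at least a threshold fraction of samples of
any requested cancer type, with the selection unioned over types.

The refit is exposed as a small model/results pair: build
:class:`SignatureRefit` from a spectrum matrix and a definition matrix,
call :meth:`SignatureRefit.fit`, and read absolute/relative contributions
and reconstruction residuals off the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .contexts import ContextSpectrum
from .io import SignatureModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------


def select_signatures(
    exposures: pd.DataFrame,
    sample_types: pd.Series,
    types: Sequence[str],
    threshold: float = 0.10,
    presence_floor: float = 0.0,
) -> list[str]:
    """Select signatures present in at least ``threshold`` of any requested type.

    ``exposures`` is samples x signatures; ``sample_types`` maps each sample
    to its cancer type. A signature counts as present in a sample when its
    exposure exceeds ``presence_floor``. Selection is computed per type and
    unioned. Signature order of the input table is preserved.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    available = set(sample_types.unique())
    missing = [t for t in types if t not in available]
    if missing:
        raise KeyError(
            f"cancer type(s) {missing} not in exposure table; "
            f"available: {sorted(available)}"
        )
    selected: set[str] = set()
    for ctype in types:
        sub = exposures.loc[sample_types == ctype]
        if len(sub) == 0:
            continue
        frac_present = (sub > presence_floor).mean(axis=0)
        selected |= set(frac_present.index[frac_present >= threshold])
    return [s for s in exposures.columns if s in selected]


# ---------------------------------------------------------------------------
# NNLS refit
# ---------------------------------------------------------------------------


@dataclass
class SignatureFit:
    """Per-clone refit result: absolute contributions (mutation counts
    attributed to each signature), relative fractions, and the Euclidean
    distance between the observed and reconstructed spectrum."""

    clone_id: str
    signatures: list[str]
    absolute: np.ndarray
    residual: float
    all_zero: bool = False

    @property
    def relative(self) -> np.ndarray:
        total = self.absolute.sum()
        if total == 0:
            return np.zeros_like(self.absolute)
        return self.absolute / total


def fit_nnls(spectrum: ContextSpectrum | np.ndarray,
             model: SignatureModel) -> SignatureFit:
    """Fit one spectrum to the model's signatures by non-negative least squares.

    Accepts a ContextSpectrum (catalog checked against the definitions) or a
    bare count vector in catalog order (may be non-integer, e.g. an exact
    mixture). All-zero spectra return a zero fit flagged ``all_zero``.
    Deterministic (active-set solver, no randomness).
    """
    if isinstance(spectrum, ContextSpectrum):
        if list(model.contexts) != list(spectrum.catalog):
            raise ValueError(
                f"definition contexts ({len(model.contexts)}) do not match "
                f"the spectrum catalog ({len(spectrum.catalog)})"
            )
        counts = spectrum.counts.astype(float)
        clone_id = spectrum.clone_id
    else:
        counts = np.asarray(spectrum, dtype=float)
        clone_id = "sample"
        if counts.shape != (len(model.contexts),):
            raise ValueError(
                f"count vector length {counts.shape} does not match "
                f"{len(model.contexts)} contexts"
            )
    if counts.sum() == 0:
        return SignatureFit(
            clone_id, list(model.signatures),
            np.zeros(len(model.signatures)), 0.0, all_zero=True,
        )
    x, rnorm = nnls(model.definitions, counts)
    return SignatureFit(clone_id, list(model.signatures), x, float(rnorm))


def relative_contributions(fits: Sequence[SignatureFit]) -> pd.DataFrame:
    """Stack per-clone relative contributions into a signatures x clones table.

    Columns sum to 1 except for flagged all-zero clones, whose columns are
    all-zero (and logged).
    """
    if not fits:
        return pd.DataFrame()
    names = fits[0].signatures
    for f in fits:
        if f.signatures != names:
            raise ValueError("fits do not share a signature list")
    data = {}
    for f in fits:
        if f.all_zero:
            logger.warning("clone %s has an empty spectrum; relative "
                           "contributions reported as zeros", f.clone_id)
        data[f.clone_id] = f.relative
    return pd.DataFrame(data, index=names)


def absolute_contributions(fits: Sequence[SignatureFit]) -> pd.DataFrame:
    """Stack per-clone absolute contributions into a signatures x clones table."""
    if not fits:
        return pd.DataFrame()
    return pd.DataFrame({f.clone_id: f.absolute for f in fits},
                        index=fits[0].signatures)


# ---------------------------------------------------------------------------
# Model / results wrappers
# ---------------------------------------------------------------------------


class SignatureRefit:
    """Signature refitting model over a spectrum matrix.

    Parameters
    ----------
    spectra : pd.DataFrame
        Context x clone count matrix (rows in catalog order).
    model : SignatureModel
        Definition matrix whose contexts match the spectrum rows.
    """

    def __init__(self, spectra: pd.DataFrame, model: SignatureModel,
                 var_class: str = "SBS"):
        if list(spectra.index) != list(model.contexts):
            raise ValueError("spectrum rows do not match definition contexts")
        self.spectra = spectra
        self.model = model
        self.var_class = var_class

    @classmethod
    def from_spectra(cls, spectra: Sequence[ContextSpectrum], model: SignatureModel
                     ) -> "SignatureRefit":
        matrix = pd.DataFrame(
            {s.clone_id: s.counts for s in spectra}, index=list(model.contexts)
        )
        return cls(matrix, model)

    def fit(self) -> "SignatureRefitResults":
        fits = []
        for clone_id in self.spectra.columns:
            spec = ContextSpectrum(
                clone_id=str(clone_id),
                var_class=self.var_class,
                catalog=tuple(self.spectra.index),
                counts=self.spectra[clone_id].to_numpy(),
            )
            fits.append(fit_nnls(spec, self.model))
        return SignatureRefitResults(self, fits)


@dataclass
class SignatureRefitResults:
    model: SignatureRefit
    fits: list[SignatureFit] = field(default_factory=list)

    @property
    def absolute(self) -> pd.DataFrame:
        return absolute_contributions(self.fits)

    @property
    def relative(self) -> pd.DataFrame:
        return relative_contributions(self.fits)

    @property
    def residuals(self) -> pd.Series:
        return pd.Series({f.clone_id: f.residual for f in self.fits}, name="residual")

    def summary(self) -> str:
        lines = ["Signature refit (non-negative least squares)"]
        lines.append(f"  clones:     {len(self.fits)}")
        lines.append(f"  signatures: {', '.join(self.model.model.signatures)}")
        rel = self.relative
        mean_rel = rel.mean(axis=1)
        lines.append("  mean relative contribution:")
        for sig, val in mean_rel.items():
            lines.append(f"    {sig:<12} {val:6.3f}")
        lines.append(f"  median residual: {self.residuals.median():.3f}")
        return "\n".join(lines)
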