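"""Natural-isotope correction of simulated MIDs.

GC-MS fragments of derivatized amino acids carry many atoms besides the
traced carbon backbone (derivatization carbons, Si, H, N, O...).  Naturally
occurring heavy isotopes of those atoms shift the measured mass
distribution.  Rather than deflating the measurements, simulated backbone
MIDs are inflated by convolution with the fragment's natural mass-shift
distribution and then truncated to the number of mass isotopomers actually
reported, so residuals are formed on like-for-like vectors.  The truncated
vector is deliberately not renormalized, matching how truncated measured
vectors are reported.
"""

from __future__ import annotations

import numpy as np

from .model_io import CorrectionSpec, ModelError

__all__ = ["natural_mid", "apply_correction", "correction_vector"]


def natural_mid(element_specs) -> np.ndarray:
    """Mass-shift distribution of a set of atoms at natural abundance.

    ``element_specs`` is a list of ``(abundance_vector, atom_count)`` pairs;
    the result is the count-fold self-convolution per element, convolved
    across elements.  Zero atoms of every element gives the identity ``[1]``.
    """
    out = np.array([1.0])
    for vec, count in element_specs:
        if count < 0:
            raise ModelError(f"negative atom count {count}")
        a = np.asarray(vec, float)
        if (a < 0).any() or abs(a.sum() - 1.0) > 1e-9:
            raise ModelError(
                f"abundance vector must be nonnegative and sum to 1, got {vec}")
        for _ in range(int(count)):
            out = np.convolve(out, a)
    return out


def correction_vector(spec: CorrectionSpec) -> np.ndarray:
    """Natural mass-shift distribution of a fragment's non-traced atoms."""
    return natural_mid(spec.elements)


def apply_correction(simulated: np.ndarray, spec: CorrectionSpec) -> np.ndarray:
    """Convolve a simulated backbone MID with the fragment's correction
    vector and truncate to the first ``n_measured`` entries (no
    renormalization)."""
    corrected = np.convolve(np.asarray(simulated, float), correction_vector(spec))
    if spec.n_measured > len(corrected):
        raise ModelError(
            f"fragment {spec.fragment_id}: n_measured {spec.n_measured} "
            f"exceeds corrected vector length {len(corrected)}")
    return corrected[:spec.n_measured]
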