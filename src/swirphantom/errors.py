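"""Named failure modes shared across the package.

Every contract violation raises a distinct exception type so callers (and the
CLI) can report precisely what went wrong instead of catching bare ValueError.
"""


class SwirPhantomError(Exception):
    """Base class for all package-specific failures."""


class HeaderError(SwirPhantomError):
    """ENVI header missing, unreadable, or lacking a required field."""


class WavelengthMismatchError(HeaderError):
    """Declared band count disagrees with the wavelength list length."""


class UnsupportedInterleaveError(HeaderError):
    """Interleave keyword is not one of bsq/bil/bip."""


class DimensionMismatchError(SwirPhantomError):
    """Payload size or mask shape inconsistent with declared dimensions."""


class NonFiniteError(SwirPhantomError):
    """NaN or infinity where finite reflectance is required."""


class OutOfRangeError(SwirPhantomError):
    """Requested wavelength falls outside the cube's spectral range."""


class SceneError(SwirPhantomError):
    """Phantom scene parameters violate their geometric/optical contract."""


class ConstantMapError(SwirPhantomError):
    """Otsu thresholding requested on a constant-valued map."""


class UndefinedIndexError(SwirPhantomError):
    """Tanimoto index of two empty masks (0/0) is undefined."""


class SingularDesignError(SwirPhantomError):
    """Endmember matrix is rank-deficient or numerically unusable."""


class NonConvergenceError(SwirPhantomError):
    """Iterative solver exhausted its iteration budget."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NumericalError(SwirPhantomError):
    """A quantity that must be positive by theory came out non-positive."""
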