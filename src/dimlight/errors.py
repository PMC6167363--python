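"""Typed exceptions raised across the dimlight pipeline.

Every reader, estimator and test raises one of these instead of a bare
``ValueError`` so callers (and the CLI) can react to specific failure
modes.  All inherit from :class:`DimlightError`.
"""


class DimlightError(Exception):
    """Base class for all dimlight-specific errors."""


# --- core_io -------------------------------------------------------------
class RaggedAlignment(DimlightError):
    """Sequences in an alignment have unequal lengths."""


class DuplicateTaxon(DimlightError):
    """Two alignment records share the same name."""


class EmptyFile(DimlightError):
    """An input file contained no usable records."""


class ParseError(DimlightError):
    """A file could not be parsed in its declared format."""


class FewerThanThreeTips(DimlightError):
    """An unrooted tree needs at least three tips."""


class MissingColumn(DimlightError):
    """A required column is absent from a tabular input."""


class NonMonotoneTime(DimlightError):
    """Time points within one trace are not strictly increasing."""


# --- synthetic_data ------------------------------------------------------
class InvalidRates(DimlightError):
    """A ground-truth kinetic rate is non-positive."""


class InvalidLambdaMax(DimlightError):
    """Requested absorbance peak lies outside the supported range."""


# --- kinetics ------------------------------------------------------------
class FitDidNotConverge(DimlightError):
    """Nonlinear least squares failed to converge."""


class DegenerateSignal(DimlightError):
    """Signal range too small for an exponential fit to be identifiable."""


class AssayMismatch(DimlightError):
    """Traces passed to an estimator carry the wrong assay label."""


class MissingReference(DimlightError):
    """The reference pigment is absent from a comparison table."""


class NonpositiveDenominator(DimlightError):
    """v_light or k_d is non-positive; the rate ratio is undefined."""


# --- spectra -------------------------------------------------------------
class FlatSpectrum(DimlightError):
    """No absorbance band detectable above the noise floor."""


class GridMismatch(DimlightError):
    """Two spectra do not share an identical wavelength grid."""


class MissingTimeZero(DimlightError):
    """A decay series lacks the t = 0 reference spectrum."""


class ZeroReference(DimlightError):
    """The t = 0 difference absorbance is zero; fractions are undefined."""


# --- phylo_likelihood ----------------------------------------------------
class AsymmetricTable(DimlightError):
    """An exchangeability table is not symmetric (or has negative entries)."""


class BadFrequencies(DimlightError):
    """Stationary frequencies are invalid (negative or do not sum to 1)."""


class BadShape(DimlightError):
    """Gamma shape parameter must be positive."""


class TaxonMismatch(DimlightError):
    """Tree tips and alignment taxa do not agree."""


class TooManyTips(DimlightError):
    """Exhaustive enumeration requested beyond the supported tip count."""


# --- topology_tests ------------------------------------------------------
class EmptyMatrix(DimlightError):
    """A site-likelihood matrix has no sites or no topologies."""
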