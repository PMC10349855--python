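"""Exception hierarchy for prelink."""


class PrelinkError(Exception):
    """Base class for all package errors."""


class StructureFormatError(PrelinkError):
    """Unparsable or unsupported coordinate file content."""


class EmptyInputError(PrelinkError):
    """An operation received an empty model, table or set."""


class CapacityError(PrelinkError):
    """Output format cannot represent the object (e.g. >99999 atoms in PDB)."""


class InsufficientPairsError(PrelinkError):
    """Fewer than three paired atoms available for superposition."""


class DomainViolationError(PrelinkError):
    """A torsion was requested for a residue outside the flexible segments."""


class EmptyOverlapError(PrelinkError):
    """Two tables share no residues."""


class OutOfRegimeError(PrelinkError):
    """A quantity lies outside the validity regime of the estimator."""


class GuinierError(PrelinkError):
    """No valid Guinier regime could be found in a scattering curve."""


class TransformFailureError(PrelinkError):
    """Indirect Fourier transform did not converge."""


class FitError(PrelinkError):
    """A nonlinear fit failed to converge."""


class ConfigurationError(PrelinkError):
    """Missing or inconsistent parameters."""


class SizeError(PrelinkError):
    """A collection is too small for the requested operation."""


class SamplingError(PrelinkError):
    """Conformer sampling cannot proceed (e.g. no flexible residues)."""
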