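"""Exception hierarchy for the fetalmorph pipeline."""


class FetalmorphError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FetalmorphError):
    """A file does not conform to the expected on-disk format."""


class GeometryError(FetalmorphError):
    """Degenerate or inconsistent geometry (singular affine, collinear plane points, ...)."""


class ParameterError(FetalmorphError):
    """A phantom or algorithm parameter violates its invariants."""


class EmptyStructureError(FetalmorphError):
    """A requested labeled structure contains no voxels."""


class LandmarkError(FetalmorphError):
    """A required landmark is missing or degenerate."""


class RegistrationError(FetalmorphError):
    """Point-set registration failed or the geometry is degenerate."""


class ConnectivityError(FetalmorphError):
    """A mesh operation requires a connected mesh."""


class NumericError(FetalmorphError):
    """A numerical solver failed to converge."""


class SampleSizeError(FetalmorphError):
    """A statistical routine received too small or degenerate a sample."""


class LabelTransferError(FetalmorphError):
    """Parcellation reference labels are missing or inconsistent."""
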