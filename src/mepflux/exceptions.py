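"""Exception hierarchy shared across mepflux modules."""


class MepfluxError(Exception):
    """Base class for all package-specific errors."""


class DegeneratePoolsError(MepfluxError):
    """Two pool sizes are too close for the partial-fraction closed form."""


class IntegrationError(MepfluxError):
    """The ODE integrator could not meet its tolerance."""


class NoPlastidialReferenceError(MepfluxError):
    """Isoprene final labeling fraction is zero; ratios are undefined."""


class MissingMetaboliteError(MepfluxError):
    """A required metabolite is absent from the pool table."""


class DuplicateMetaboliteError(MepfluxError):
    """A metabolite appears more than once in the pool table."""


class ZeroPoolError(MepfluxError):
    """A plastidial pool computed to zero; the flux model needs positive pools."""


class NoIncorporationError(MepfluxError):
    """The labeling time course shows no detectable label incorporation."""


class AllZeroProductError(MepfluxError):
    """Progress-curve product concentrations are all zero."""


class InsufficientLevelsError(MepfluxError):
    """Too few distinct substrate levels for a Michaelis-Menten fit."""


class ZeroVelocityError(MepfluxError):
    """A zero initial velocity cannot enter a double-reciprocal transform."""


class MissingEnzymeMolarityError(MepfluxError):
    """kcat requested without a positive enzyme molar concentration."""


class MissingKcatError(MepfluxError):
    """Catalytic-efficiency comparison requires kcat on both operands."""


class ZeroDmadpError(MepfluxError):
    """DMADP amount must be positive to normalize a product ratio."""


class InvalidClassError(MepfluxError):
    """Unknown prenyl diphosphate class."""


class NegativeMolesError(MepfluxError):
    """Product profile contains negative mole amounts."""


class ZeroDemandError(MepfluxError):
    """Demand profile consumes neither DMADP nor IDP."""


class SchemaError(MepfluxError):
    """An input table does not match the expected CSV schema."""
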