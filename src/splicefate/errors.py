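"""Exception hierarchy shared across the package."""


class SpliceFateError(Exception):
    """Base class for all package errors."""


class GeneNotFoundError(SpliceFateError):
    """Requested gene id is absent from the annotation."""


class MalformedAnnotationError(SpliceFateError):
    """Annotation violates a structural invariant (bad strand, exon outside span...)."""


class ReferenceMismatchError(SpliceFateError):
    """Variant ref allele does not match the genome sequence."""


class InputError(SpliceFateError):
    """Caller-supplied value violates a precondition."""


class InternalConsistencyError(SpliceFateError):
    """Two internally produced artifacts disagree (track/map lengths...)."""


class InvalidPathError(SpliceFateError):
    """A splice path violates ordering/overlap constraints."""
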