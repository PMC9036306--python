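"""Exception hierarchy. Everything derives from SkinQuantError; errors that are
really argument-validation failures also derive from ValueError so callers can
catch either."""


class SkinQuantError(Exception):
    pass


class CalibrationError(SkinQuantError, ValueError):
    pass


class ImageIOError(SkinQuantError, ValueError):
    pass


class AnnotationError(SkinQuantError, ValueError):
    pass


class GeometryError(SkinQuantError, ValueError):
    pass


class StainClassificationError(SkinQuantError, ValueError):
    pass


class QuantificationError(SkinQuantError, ValueError):
    pass


class DensityError(SkinQuantError, ValueError):
    pass


class AgreementError(SkinQuantError, ValueError):
    pass


class SyntheticDataError(SkinQuantError, ValueError):
    pass


class PipelineError(SkinQuantError, RuntimeError):
    pass
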