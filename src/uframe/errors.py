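"""Exception types shared across the package."""


class UFrameError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(UFrameError, ValueError):
    """Image/region/patch geometry cannot satisfy the requested operation."""


class DegenerateDistributionError(UFrameError, ValueError):
    """All sampling scores vanished; caller should fall back to uniform sampling."""


class ContractError(UFrameError, ValueError):
    """An argument violates a documented precondition."""


class RankDeficiencyError(UFrameError, ValueError):
    """Point correspondences are insufficient or collinear for an affine fit."""


class UndefinedCorrelationError(UFrameError, ValueError):
    """Pearson correlation is undefined (constant input)."""


class MemoryFloorError(UFrameError, ValueError):
    """Region count would exceed the configured discriminator head cap."""
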