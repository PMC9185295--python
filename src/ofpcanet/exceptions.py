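"""Exception hierarchy for the ofpcanet pipeline.

``InputError`` covers bad user data (unreadable clips, malformed manifests),
``ConfigError`` covers invalid parameter combinations, ``FormatError`` covers
on-disk format violations (e.g. a corrupt .flo file), ``SolverError`` covers
numerical failures inside the flow solver, and ``StateError`` covers use of
objects before they are ready (e.g. an untrained filter bank).
"""


class OFPCANetError(Exception):
    """Base class for all ofpcanet errors."""


class InputError(OFPCANetError, ValueError):
    pass


class ConfigError(OFPCANetError, ValueError):
    pass


class FormatError(OFPCANetError, ValueError):
    pass


class SolverError(OFPCANetError, RuntimeError):
    pass


class StateError(OFPCANetError, RuntimeError):
    pass
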