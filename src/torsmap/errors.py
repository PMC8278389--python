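"""Exception hierarchy."""


class TorsmapError(Exception):
    """Base class for all torsmap errors."""


class MissingColumnError(TorsmapError, KeyError):
    """A requested named column is absent from the input file."""


class ColvarParseError(TorsmapError, ValueError):
    """Malformed trajectory file (ragged row, non-numeric entry, bad header)."""


class EmptyInputError(TorsmapError, ValueError):
    """Input file or array contains no data."""


class FormatError(TorsmapError, ValueError):
    """Serialized artifact fails validation (version, checksum, normalization)."""


class NoBarrierError(TorsmapError, ValueError):
    """Barrier extraction requested on a unimodal free-energy profile."""


class TuningError(TorsmapError, ValueError):
    """The neighbor-fraction target cannot be realized on this distance matrix."""


class SelectionError(TorsmapError, ValueError):
    """Cluster-center selection produced zero centers."""


class StageError(TorsmapError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
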