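"""Named exceptions shared across the package."""


class AutozygomapError(Exception):
    """Base class for all package errors."""


class PedigreeError(AutozygomapError):
    """Structurally invalid pedigree (cycle, dangling parent, bad founder)."""


class UnknownIndividualError(PedigreeError):
    """An individual id was requested that is not in the pedigree."""


class UnsupportedUnionError(PedigreeError):
    """Requested consanguineous union type is not supported."""


class PanelError(AutozygomapError):
    """Marker panel violates its invariants or lacks a chromosome."""


class SampleNotFoundError(AutozygomapError):
    """Sample id absent from a genotype matrix."""


class SimulationError(AutozygomapError):
    """Gene-dropping simulation failure."""


class RetryLimitError(SimulationError):
    """Rejection sampling exceeded the configured retry cap."""


class VcfParseError(AutozygomapError):
    """Malformed VCF content; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class PedParseError(AutozygomapError):
    """Malformed 6-column PED file."""


class NotHomozygousError(AutozygomapError):
    """A carrier sample is not homozygous at the focal variant."""


class MappingError(AutozygomapError):
    """Invalid input to the homozygosity-mapping score."""


class ConfigError(AutozygomapError):
    """Invalid pipeline configuration."""


class PipelineStageError(AutozygomapError):
    """A pipeline stage failed; names the stage and input context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
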