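"""Exception hierarchy shared across the toolkit.

Errors are split by origin so the CLI can map them to distinct exit codes:
configuration problems (bad crypto/protocol parameters), input format
problems, and evaluation-time problems (missing or inconsistent artifacts).
"""


class PrivkmerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PrivkmerError):
    """Invalid cryptographic or protocol parameters."""


class FormatError(PrivkmerError):
    """Malformed input file (FASTA/FASTQ/MEME/query list)."""


class UsageError(PrivkmerError):
    """API misuse: mismatched contexts, wrong ciphertext size, bad mode."""


class KeyMismatchError(UsageError):
    """Decryption attempted with key material from a different context."""


class EvaluationError(PrivkmerError):
    """Server-side evaluation failure (missing stride, broken deployment)."""


class IncompleteResultsError(PrivkmerError):
    """Client found gaps in the server's results directory."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            f"{len(self.missing)} result file(s) missing, e.g. {self.missing[:3]}"
        )
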