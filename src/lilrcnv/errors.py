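"""Package-wide exception types.

``LilrError`` marks data-level failures (malformed input, inconsistent trio,
zero coverage, ...). The CLI maps it to exit code 1; usage errors stay with
click's exit code 2.
"""


class LilrError(Exception):
    """A data or model error attributable to the input, not to usage."""


class InconsistentTrioError(LilrError):
    """No Mendelian-consistent parental configuration explains the trio.

    Signals either a de-novo CNV or an upstream genotyping error; de-novo
    events are deliberately not modelled.
    """
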