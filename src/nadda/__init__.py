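"""nadda: alignment-free detection of conserved regions in protein sequences.

The pipeline converts each sequence into a k-mer frequency profile, classifies
every residue index as conserved or not with a random-subspace ensemble of
decision trees over a sliding window of profile values, and emits maximal
conserved regions plus per-index accuracy/sensitivity/specificity evaluation
against reference annotations.
"""

__version__ = "0.1.0"

from . import errors  # noqa: F401

_LAZY = {
    "sequence_io",
    "kmer_profile",
    "featurize",
    "model",
    "regions_eval",
    "synthetic",
    "cli",
}


def __getattr__(name):
    # submodules are imported lazily so that `import nadda` stays cheap
    if name in _LAZY:
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
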