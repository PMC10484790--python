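"""Optional adapter that plugs a real 650M-parameter transformer model
behind the :func:`plmvep.backend.score_sequence` contract.

Requires ``torch`` and ``fair-esm`` (not installed by default) plus a
weights download, so it is excluded from the core test suite. Token
convention: the model's begin/end-of-sequence tokens are appended around
the residue tokens and their logit rows are dropped, so window edges see
exactly the window subsequence, mirroring the synthetic backend.
"""

from __future__ import annotations

import numpy as np

from .backend import ALPHABET, BackendSpec, PositionLogProbs, ProteinSequence
from .errors import SequenceLengthError, ValidationError


def load_real_backend(max_input_length: int = 1022) -> BackendSpec:
    return BackendSpec(kind="real-model-adapter", max_input_length=max_input_length)


class EsmScorer:
    """Lazy wrapper over the pretrained 650M-parameter model."""

    def __init__(self, model_name: str = "esm1b_t33_650M_UR50S"):
        try:
            import esm  # type: ignore
            import torch  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the real-model adapter needs the optional 'torch' and "
                "'fair-esm' packages"
            ) from exc
        self._torch = torch
        self.model, self.alphabet = esm.pretrained.load_model_and_alphabet(model_name)
        self.model.eval()
        self.batch_converter = self.alphabet.get_batch_converter()
        self._aa_token_idx = [self.alphabet.get_idx(aa) for aa in ALPHABET]

    def score_sequence(
        self, backend: BackendSpec, seq: ProteinSequence
    ) -> PositionLogProbs:  # pragma: no cover - needs weights
        if backend.kind != "real-model-adapter":
            raise ValidationError("backend is not a real-model adapter")
        if len(seq) > backend.max_input_length:
            raise SequenceLengthError(
                f"sequence {seq.id!r} exceeds the model limit; tile it first"
            )
        torch = self._torch
        _, _, tokens = self.batch_converter([(seq.id, seq.residues)])
        with torch.no_grad():
            logits = self.model(tokens)["logits"][0]
        # drop BOS/EOS rows, keep canonical amino-acid columns only
        rows = logits[1 : len(seq) + 1, self._aa_token_idx]
        log_probs = torch.log_softmax(rows, dim=-1).cpu().numpy().astype(np.float64)
        return PositionLogProbs(sequence_id=seq.id, matrix=log_probs)
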