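"""Gene-scaffold generator: a sequence-to-sequence model that conditions
molecular-scaffold SMILES generation on a 978-gene phenotype vector.

Architecture
------------
* **Encoder** — the discrete phenotype vector (entries in {-1,0,1}) is
  pooled into non-overlapping windows, run through a two-layer LSTM, and the
  final-layer outputs at ``n_c`` evenly spaced positions are projected to a
  context matrix ``c`` of shape (n_c, n_H).
* **Attention** — at every decoding step a single-layer network scores the
  context positions from the concatenated token embedding and decoder hidden
  state; softmax weights pool the context rows into one feature vector.
* **Stack-augmented LSTM decoder** — a standard LSTM cell whose input is the
  token embedding, the attention feature and the current stack top.  After
  each step the differentiable stack (n_s rows of width n_H) is updated by a
  soft mixture of push / pop / no-op, which helps the model track nested
  SMILES syntax (ring closures, branches) and keeps the validity of sampled
  strings high.

Training is teacher-forced in two stages: *pretrain* fits the decoder alone
(zero context) on scaffolds so it learns SMILES grammar; *finetune* trains
encoder and decoder jointly on (phenotype, scaffold) pairs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .chem import VOCAB, TokenVocabulary
from .nn import (LSTM, Embedding, Linear, LSTMCell, Module, RMSprop, Tensor,
                 concat, clip_grad_norm, softmax_cross_entropy)
from .phenotype import PhenotypeVector

__all__ = ["GSGConfig", "GSG", "AttentionState", "StackState", "DecoderState",
           "GeneratedScaffold", "stack_update", "train_gsg", "generate_scaffolds"]

# stack control indices: order (no-op, push, pop); pop last so that the
# "s_ctrl[-1]" of the update equations is the pop weight
NOOP, PUSH, POP = 0, 1, 2


@dataclass
class GSGConfig:
    n_c: int = 16          # context positions
    n_H: int = 256         # hidden width (context, decoder, stack rows)
    n_genes: int = 978     # phenotype vector length
    n_s: int = 10          # stack depth
    emb_dim: int = 128     # token embedding
    enc_layers: int = 2
    enc_window: int = 6    # genes pooled per encoder input step
    max_len: int = 100     # generation stops beyond this many tokens
    lr: float = 1e-4
    batch_size: int = 128
    grad_clip: float = 5.0
    loss: str = "ce"       # "ce" (categorical) or "bce" (per-token one-hot)
    seed: int = 0


@dataclass
class AttentionState:
    scores: np.ndarray    # (n_c,)
    weights: np.ndarray   # softmax of scores, on the simplex
    pooled: np.ndarray    # (n_H,) weighted combination of context rows


@dataclass
class StackState:
    stack: Tensor         # (batch, n_s, n_H)


@dataclass
class DecoderState:
    h: Tensor
    c: Tensor
    stack: Tensor
    position: int = 0


@dataclass(frozen=True)
class GeneratedScaffold:
    smiles: str
    valid: bool


def stack_update(stack, s_stack, s_ctrl):
    """One differentiable stack step.

    ``stack``: (B, n_s, H); ``s_stack``: (B, H) candidate top; ``s_ctrl``:
    (B, 3) simplex weights ordered (no-op, push, pop).  New top is
    ``ctrl[pop]*s[1] + ctrl[push]*s_stack + ctrl[noop]*s[0]``; the body
    shifts down under push and up under pop, with zeros filling the bottom
    row on pop.  Accepts Tensors (differentiable) or plain arrays.
    """
    t = lambda x: x if isinstance(x, Tensor) else Tensor(x)
    stack, s_stack, s_ctrl = t(stack), t(s_stack), t(s_ctrl)
    B, n_s, H = stack.shape
    zeros = Tensor(np.zeros((B, 1, H)))
    top = s_stack.reshape(B, 1, H)
    pushed = concat([top, stack[:, : n_s - 1, :]], axis=1)       # s'[i] = s[i-1]
    popped = concat([stack[:, 1:, :], zeros], axis=1)            # s'[i] = s[i+1]
    w = lambda i: s_ctrl[:, i].reshape(B, 1, 1)
    return w(NOOP) * stack + w(PUSH) * pushed + w(POP) * popped


class PhenotypeEncoder(Module):
    def __init__(self, cfg: GSGConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.lstm = LSTM(cfg.enc_window, cfg.n_H, cfg.enc_layers, rng)
        self.proj = Linear(cfg.n_H, cfg.n_H, rng)

    def __call__(self, g: np.ndarray) -> Tensor:
        """Phenotype batch (B, 978) -> context (B, n_c, n_H)."""
        cfg = self.cfg
        B, n_genes = g.shape
        if n_genes != cfg.n_genes:
            raise ValueError(f"phenotype vector has {n_genes} genes, expected {cfg.n_genes}")
        w = cfg.enc_window
        n_steps = -(-n_genes // w)
        padded = np.zeros((B, n_steps * w))
        padded[:, :n_genes] = g
        steps = [Tensor(padded[:, i * w : (i + 1) * w]) for i in range(n_steps)]
        outputs, _ = self.lstm(steps)
        idx = np.linspace(0, n_steps - 1, cfg.n_c).round().astype(int)
        rows = [self.proj(outputs[i]).tanh().reshape(B, 1, cfg.n_H) for i in idx]
        return concat(rows, axis=1)


class GSG(Module):
    """Full generator; see the module docstring for the architecture."""

    def __init__(self, cfg: GSGConfig | None = None, vocab: TokenVocabulary = VOCAB):
        self.cfg = cfg or GSGConfig()
        self.vocab = vocab
        rng = np.random.default_rng(self.cfg.seed)
        c = self.cfg
        self.encoder = PhenotypeEncoder(c, rng)
        self.embed = Embedding(len(vocab), c.emb_dim, rng)
        self.attn = Linear(c.emb_dim + c.n_H, c.n_c, rng)
        self.cell = LSTMCell(c.emb_dim + 2 * c.n_H, c.n_H, rng)
        self.init_h = Linear(c.n_H, c.n_H, rng)
        self.init_c = Linear(c.n_H, c.n_H, rng)
        self.d_stack = Linear(c.n_H, c.n_H, rng)
        self.d_ctrl = Linear(c.n_H, 3, rng)
        self.out = Linear(c.n_H, len(vocab), rng)
        self.trained = False

    # ------------------------------------------------------------------ parts
    def encode_phenotype(self, g: PhenotypeVector | np.ndarray) -> Tensor:
        vals = np.asarray(g.values if isinstance(g, PhenotypeVector) else g, dtype=float)
        if vals.ndim == 1:
            vals = vals[None, :]
        return self.encoder(vals)

    def attend(self, e_D: Tensor, h: Tensor, context: Tensor) -> tuple[Tensor, Tensor]:
        """Attention scores -> simplex weights -> pooled context feature.
        Returns (weights, pooled) as Tensors of shape (B, n_c), (B, n_H)."""
        scores = self.attn(concat([e_D, h], axis=1))
        weights = scores.softmax(axis=1)
        B, n_c = weights.shape
        pooled = (weights.reshape(B, n_c, 1) * context).sum(axis=1)
        return weights, pooled

    def zero_context(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.cfg.n_c, self.cfg.n_H)))

    def init_state(self, batch: int, context: Tensor | None = None) -> DecoderState:
        """Decoder start state; with a context, the hidden/cell states are
        seeded from the mean context row so conditioning does not rely on
        attention alone (zero context yields a learned constant start)."""
        if context is None:
            h, c = self.cell.zeros(batch)
        else:
            pooled = context.mean(axis=1)
            h = self.init_h(pooled).tanh()
            c = self.init_c(pooled).tanh()
        stack = Tensor(np.zeros((batch, self.cfg.n_s, self.cfg.n_H)))
        return DecoderState(h=h, c=c, stack=stack, position=0)

    def decode_step(self, state: DecoderState, token_ids: np.ndarray, context: Tensor
                    ) -> tuple[Tensor, DecoderState, Tensor]:
        """One decoding step for inspection or sampling.

        Returns (next-token distribution summing to 1, advanced state,
        attention weights).
        """
        logits, new_state, weights = self._step(state, token_ids, context)
        return logits.softmax(axis=1), new_state, weights

    def _step(self, state: DecoderState, token_ids: np.ndarray, context: Tensor
              ) -> tuple[Tensor, DecoderState, Tensor]:
        """decode_step in logits space (used by training and sampling)."""
        token_ids = np.atleast_1d(np.asarray(token_ids))
        if token_ids.min() < 0 or token_ids.max() >= len(self.vocab):
            raise ValueError("token index outside vocabulary")
        e = self.embed(token_ids)
        weights, pooled = self.attend(e, state.h, context)
        top = state.stack[:, 0, :]
        h, c = self.cell(concat([e, pooled, top], axis=1), state.h, state.c)
        s_stack = self.d_stack(h).tanh()
        s_ctrl = self.d_ctrl(h).softmax(axis=1)
        new_stack = stack_update(state.stack, s_stack, s_ctrl)
        logits = self.out(h)
        return logits, DecoderState(h=h, c=c, stack=new_stack, position=state.position + 1), weights

    # --------------------------------------------------------------- training
    def _batch_ids(self, smiles_list: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Teacher-forcing arrays: inputs (B,T) '<'+body, targets body+'>',
        mask 0 on padding."""
        v = self.vocab
        seqs = [[v.bos_id] + v.encode(s) + [v.eos_id] for s in smiles_list]
        T = max(len(s) for s in seqs) - 1
        B = len(seqs)
        inp = np.full((B, T), v.pad_id, dtype=int)
        tgt = np.full((B, T), v.pad_id, dtype=int)
        mask = np.zeros((B, T))
        for i, s in enumerate(seqs):
            L = len(s) - 1
            inp[i, :L] = s[:-1]
            tgt[i, :L] = s[1:]
            mask[i, :L] = 1.0
        return inp, tgt, mask

    def _sequence_loss(self, inp, tgt, mask, context) -> Tensor:
        state = self.init_state(inp.shape[0], context)
        logit_steps = []
        for t in range(inp.shape[1]):
            logits, state, _ = self._step(state, inp[:, t], context)
            logit_steps.append(logits)
        all_logits = concat(logit_steps, axis=0)  # (T*B, V) time-major blocks
        order = np.concatenate([tgt[:, t] for t in range(tgt.shape[1])])
        m = np.concatenate([mask[:, t] for t in range(mask.shape[1])])
        if self.cfg.loss == "bce":
            return _onehot_bce(all_logits, order, m, len(self.vocab))
        return softmax_cross_entropy(all_logits, order, m)

    # --------------------------------------------------------------- sampling
    def generate(self, g: PhenotypeVector | np.ndarray | None, n: int,
                 temperature: float = 1.0, seed: int = 0, greedy: bool = False
                 ) -> list[GeneratedScaffold]:
        """Sample ``n`` scaffold SMILES conditioned on phenotype ``g``
        (``None`` draws unconditionally, as after pretraining)."""
        from rdkit import Chem

        if not self.trained:
            raise RuntimeError("model is untrained; call train_gsg first")
        rng = np.random.default_rng(seed)
        v = self.vocab
        context = self.zero_context(n) if g is None else _tile_context(self.encode_phenotype(g), n)
        state = self.init_state(n, context)  # zero context -> learned constant start
        tokens = np.full(n, v.bos_id, dtype=int)
        done = np.zeros(n, dtype=bool)
        bodies: list[list[int]] = [[] for _ in range(n)]
        for _ in range(self.cfg.max_len):
            logits, state, _ = self._step(state, tokens, context)
            if greedy:
                nxt = logits.data.argmax(axis=1)
            else:
                z = logits.data / max(temperature, 1e-6)
                z -= z.max(axis=1, keepdims=True)
                p = np.exp(z)
                p[:, v.pad_id] = 0.0
                p /= p.sum(axis=1, keepdims=True)
                u = rng.random((n, 1))
                nxt = (p.cumsum(axis=1) < u).sum(axis=1)
            for i in range(n):
                if done[i]:
                    continue
                if nxt[i] == v.eos_id:
                    done[i] = True
                else:
                    bodies[i].append(int(nxt[i]))
            if done.all():
                break
            tokens = np.where(done, v.eos_id, nxt)
        out = []
        for body in bodies:
            smi = v.decode(body)
            valid = bool(smi) and Chem.MolFromSmiles(smi) is not None
            out.append(GeneratedScaffold(smiles=smi, valid=valid))
        return out

    # ------------------------------------------------------------ checkpoints
    def save(self, path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, config=json.dumps(asdict(self.cfg)), trained=self.trained, **arrays)

    @classmethod
    def load(cls, path, vocab: TokenVocabulary = VOCAB) -> "GSG":
        data = np.load(path, allow_pickle=False)
        cfg = GSGConfig(**json.loads(str(data["config"])))
        model = cls(cfg, vocab)
        model.load_arrays([data[f"p{i}"] for i in range(len(model.parameters()))])
        model.trained = bool(data["trained"])
        return model


def _tile_context(context: Tensor, n: int) -> Tensor:
    reps = np.repeat(context.data, n, axis=0) if context.shape[0] == 1 else context.data
    return Tensor(reps)


def _onehot_bce(logits: Tensor, targets: np.ndarray, mask: np.ndarray, n_vocab: int) -> Tensor:
    """Per-token one-hot binary cross-entropy over the vocabulary (a literal
    'binary cross-entropy' reading; categorical CE is the default)."""
    onehot = np.zeros((len(targets), n_vocab))
    onehot[np.arange(len(targets)), targets] = 1.0
    p = logits.sigmoid()
    eps = 1e-9
    per = Tensor(onehot) * (p + eps).log() + Tensor(1.0 - onehot) * (1.0 - p + eps).log()
    masked = per.sum(axis=1) * Tensor(mask)
    return -masked.sum() / max(mask.sum(), 1.0) / n_vocab


def train_gsg(pairs, stage: str, model: GSG | None = None, cfg: GSGConfig | None = None,
              epochs: int = 20, seed: int = 0, verbose: bool = False):
    """Train a generator with teacher forcing (RMSprop).

    ``pairs``: for ``stage='pretrain'`` an iterable of scaffold SMILES (any
    phenotype part is ignored and the context is zero); for
    ``stage='finetune'`` an iterable of (PhenotypeVector-or-array, smiles).
    Returns (model, per-epoch mean loss trace).
    """
    if stage not in ("pretrain", "finetune"):
        raise ValueError("stage must be 'pretrain' or 'finetune'")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training set")
    model = model or GSG(cfg)
    rng = np.random.default_rng(seed)
    if stage == "pretrain":
        smiles = [p if isinstance(p, str) else p[1] for p in pairs]
        phen = None
    else:
        phen = np.stack([np.asarray(p[0].values if isinstance(p[0], PhenotypeVector) else p[0], dtype=float)
                         for p in pairs])
        smiles = [p[1] for p in pairs]
    params = model.parameters()
    opt = RMSprop(params, lr=model.cfg.lr)
    bs = model.cfg.batch_size
    trace = []
    for _ in range(epochs):
        order = rng.permutation(len(smiles))
        losses = []
        for lo in range(0, len(order), bs):
            idx = order[lo : lo + bs]
            batch = [smiles[i] for i in idx]
            inp, tgt, mask = model._batch_ids(batch)
            context = (model.zero_context(len(idx)) if phen is None
                       else model.encoder(phen[idx]))
            model.zero_grad()
            loss = model._sequence_loss(inp, tgt, mask, context)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss {loss.data!r}")
            loss.backward()
            clip_grad_norm(params, model.cfg.grad_clip)
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {len(trace)}: loss {trace[-1]:.4f}")
    model.trained = True
    return model, trace


def generate_scaffolds(model: GSG, g: PhenotypeVector | np.ndarray | None, n: int,
                       temperature: float = 1.0, seed: int = 0) -> list[GeneratedScaffold]:
    return model.generate(g, n, temperature=temperature, seed=seed)
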