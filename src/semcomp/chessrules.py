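"""Chess rules: positions, legal-move generation, SAN and PGN.

A small, self-contained rules engine used to synthesise random legal games
and to read/write standard PGN.  Squares are indexed 0..63 rank-major from
a1; piece symbols are integers 0..12 with 0 = empty, 1..6 = white P N B R Q K,
7..12 = the black pieces in the same order.  Move generation uses the classic
120-cell mailbox with pseudo-legal generation followed by a king-safety
filter, which covers castling, en passant, promotion, check, checkmate and
stalemate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

EMPTY = 0
WP, WN, WB, WR, WQ, WK = 1, 2, 3, 4, 5, 6
BP, BN, BB, BR, BQ, BK = 7, 8, 9, 10, 11, 12

WHITE, BLACK = 0, 1

#: index -> display character; also fixes the one-hot class order used by
#: the board encoder (class 0 is the empty square).
SYMBOLS = ".PNBRQKpnbrqk"

_PIECE_LETTER = {1: "P", 2: "N", 3: "B", 4: "R", 5: "Q", 6: "K"}
_LETTER_PIECE = {v: k for k, v in _PIECE_LETTER.items()}

# --- mailbox tables -------------------------------------------------------

_MAILBOX = [-1] * 120
_MAILBOX64 = [0] * 64
for _r in range(8):
    for _f in range(8):
        _sq64 = _r * 8 + _f
        _sq120 = 21 + _r * 10 + _f
        _MAILBOX[_sq120] = _sq64
        _MAILBOX64[_sq64] = _sq120

_KNIGHT_OFF = (-21, -19, -12, -8, 8, 12, 19, 21)
_BISHOP_OFF = (-11, -9, 9, 11)
_ROOK_OFF = (-10, -1, 1, 10)
_KING_OFF = _BISHOP_OFF + _ROOK_OFF

# castling-rights bits
_W_KS, _W_QS, _B_KS, _B_QS = 1, 2, 4, 8


def is_white(piece: int) -> bool:
    return 1 <= piece <= 6


def is_black(piece: int) -> bool:
    return piece >= 7


def piece_color(piece: int) -> int:
    return WHITE if piece <= 6 else BLACK


def piece_type(piece: int) -> int:
    """Colour-free type in 1..6 (P..K)."""
    return piece - 6 if piece >= 7 else piece


def square_name(sq: int) -> str:
    return "abcdefgh"[sq % 8] + str(sq // 8 + 1)


def parse_square(name: str) -> int:
    return (int(name[1]) - 1) * 8 + "abcdefgh".index(name[0])


@dataclass(frozen=True)
class Move:
    frm: int
    to: int
    promo: int = 0  # piece *type* (2..5) or 0

    def uci(self) -> str:
        s = square_name(self.frm) + square_name(self.to)
        if self.promo:
            s += _PIECE_LETTER[self.promo].lower()
        return s


_START_BOARD = (
    [WR, WN, WB, WQ, WK, WB, WN, WR]
    + [WP] * 8
    + [EMPTY] * 32
    + [BP] * 8
    + [BR, BN, BB, BQ, BK, BB, BN, BR]
)


@dataclass
class Position:
    """Full game state: placement plus side to move, castling, en passant."""

    board: list[int] = field(default_factory=lambda: list(_START_BOARD))
    stm: int = WHITE
    castling: int = _W_KS | _W_QS | _B_KS | _B_QS
    ep: int = -1  # en-passant target square or -1
    fullmove: int = 1

    def copy(self) -> "Position":
        return Position(list(self.board), self.stm, self.castling, self.ep, self.fullmove)

    # -- attack detection --------------------------------------------------

    def attacked(self, sq: int, by: int) -> bool:
        """True if `sq` is attacked by side `by`."""
        b = self.board
        m120 = _MAILBOX64[sq]
        # pawns: a white pawn on sq-9/sq-7 attacks sq
        if by == WHITE:
            for off in (-11, -9):
                s = _MAILBOX[m120 + off]
                if s >= 0 and b[s] == WP:
                    return True
        else:
            for off in (9, 11):
                s = _MAILBOX[m120 + off]
                if s >= 0 and b[s] == BP:
                    return True
        knight = WN if by == WHITE else BN
        for off in _KNIGHT_OFF:
            s = _MAILBOX[m120 + off]
            if s >= 0 and b[s] == knight:
                return True
        king = WK if by == WHITE else BK
        for off in _KING_OFF:
            s = _MAILBOX[m120 + off]
            if s >= 0 and b[s] == king:
                return True
        bishop = WB if by == WHITE else BB
        queen = WQ if by == WHITE else BQ
        for off in _BISHOP_OFF:
            t = m120 + off
            while _MAILBOX[t] >= 0:
                p = b[_MAILBOX[t]]
                if p != EMPTY:
                    if p == bishop or p == queen:
                        return True
                    break
                t += off
        rook = WR if by == WHITE else BR
        for off in _ROOK_OFF:
            t = m120 + off
            while _MAILBOX[t] >= 0:
                p = b[_MAILBOX[t]]
                if p != EMPTY:
                    if p == rook or p == queen:
                        return True
                    break
                t += off
        return False

    def king_square(self, color: int) -> int:
        king = WK if color == WHITE else BK
        return self.board.index(king)

    def in_check(self, color: int | None = None) -> bool:
        color = self.stm if color is None else color
        return self.attacked(self.king_square(color), 1 - color)

    # -- move generation ---------------------------------------------------

    def _pseudo_moves(self) -> Iterator[Move]:
        b = self.board
        stm = self.stm
        own_low, own_high = (1, 6) if stm == WHITE else (7, 12)
        for frm in range(64):
            p = b[frm]
            if p == EMPTY or not (own_low <= p <= own_high):
                continue
            pt = piece_type(p)
            m120 = _MAILBOX64[frm]
            if pt == 1:  # pawn
                fwd = 10 if stm == WHITE else -10
                start_rank = 1 if stm == WHITE else 6
                promo_rank = 7 if stm == WHITE else 0
                one = _MAILBOX[m120 + fwd]
                if one >= 0 and b[one] == EMPTY:
                    if one // 8 == promo_rank:
                        for pr in (5, 4, 3, 2):
                            yield Move(frm, one, pr)
                    else:
                        yield Move(frm, one)
                        if frm // 8 == start_rank:
                            two = _MAILBOX[m120 + 2 * fwd]
                            if two >= 0 and b[two] == EMPTY:
                                yield Move(frm, two)
                for doff in (fwd - 1, fwd + 1):
                    cap = _MAILBOX[m120 + doff]
                    if cap < 0:
                        continue
                    tp = b[cap]
                    enemy = is_black(tp) if stm == WHITE else is_white(tp)
                    if (tp != EMPTY and enemy) or cap == self.ep:
                        if cap // 8 == promo_rank:
                            for pr in (5, 4, 3, 2):
                                yield Move(frm, cap, pr)
                        else:
                            yield Move(frm, cap)
            elif pt in (2, 6):  # knight, king
                for off in _KNIGHT_OFF if pt == 2 else _KING_OFF:
                    to = _MAILBOX[m120 + off]
                    if to < 0:
                        continue
                    tp = b[to]
                    if tp == EMPTY or not (own_low <= tp <= own_high):
                        yield Move(frm, to)
            else:  # sliders
                offs = {3: _BISHOP_OFF, 4: _ROOK_OFF, 5: _KING_OFF}[pt]
                for off in offs:
                    t = m120 + off
                    while _MAILBOX[t] >= 0:
                        to = _MAILBOX[t]
                        tp = b[to]
                        if tp == EMPTY:
                            yield Move(frm, to)
                        else:
                            if not (own_low <= tp <= own_high):
                                yield Move(frm, to)
                            break
                        t += off
        # castling
        if stm == WHITE and b[4] == WK:
            if (
                self.castling & _W_KS
                and b[5] == b[6] == EMPTY
                and b[7] == WR
                and not self.attacked(4, BLACK)
                and not self.attacked(5, BLACK)
                and not self.attacked(6, BLACK)
            ):
                yield Move(4, 6)
            if (
                self.castling & _W_QS
                and b[3] == b[2] == b[1] == EMPTY
                and b[0] == WR
                and not self.attacked(4, BLACK)
                and not self.attacked(3, BLACK)
                and not self.attacked(2, BLACK)
            ):
                yield Move(4, 2)
        elif stm == BLACK and b[60] == BK:
            if (
                self.castling & _B_KS
                and b[61] == b[62] == EMPTY
                and b[63] == BR
                and not self.attacked(60, WHITE)
                and not self.attacked(61, WHITE)
                and not self.attacked(62, WHITE)
            ):
                yield Move(60, 62)
            if (
                self.castling & _B_QS
                and b[59] == b[58] == b[57] == EMPTY
                and b[56] == BR
                and not self.attacked(60, WHITE)
                and not self.attacked(59, WHITE)
                and not self.attacked(58, WHITE)
            ):
                yield Move(60, 58)

    def make(self, move: Move) -> "Position":
        """Apply a (pseudo-)legal move, returning the successor position."""
        nxt = self.copy()
        b = nxt.board
        p = b[move.frm]
        pt = piece_type(p)
        stm = self.stm
        nxt.ep = -1
        if pt == 1:
            if move.to == self.ep and b[move.to] == EMPTY:  # en passant
                b[move.to - 8 if stm == WHITE else move.to + 8] = EMPTY
            if abs(move.to - move.frm) == 16:
                nxt.ep = (move.frm + move.to) // 2
        if pt == 6 and abs(move.to - move.frm) == 2:  # castling: move the rook
            if move.to > move.frm:
                b[move.to - 1], b[move.to + 1] = b[move.to + 1], EMPTY
            else:
                b[move.to + 1], b[move.to - 2] = b[move.to - 2], EMPTY
        b[move.to] = p
        b[move.frm] = EMPTY
        if move.promo:
            b[move.to] = move.promo + (0 if stm == WHITE else 6)
        # castling-rights updates
        for sq, bit in ((4, _W_KS | _W_QS), (60, _B_KS | _B_QS),
                        (0, _W_QS), (7, _W_KS), (56, _B_QS), (63, _B_KS)):
            if move.frm == sq or move.to == sq:
                nxt.castling &= ~bit
        if stm == BLACK:
            nxt.fullmove += 1
        nxt.stm = 1 - stm
        return nxt

    def legal_moves(self) -> list[Move]:
        out = []
        for mv in self._pseudo_moves():
            nxt = self.make(mv)
            if not nxt.attacked(nxt.king_square(self.stm), nxt.stm):
                out.append(mv)
        return out

    def is_checkmate(self) -> bool:
        return self.in_check() and not self.legal_moves()

    def is_stalemate(self) -> bool:
        return not self.in_check() and not self.legal_moves()

    def insufficient_material(self) -> bool:
        extra = [piece_type(p) for p in self.board if p not in (EMPTY, WK, BK)]
        return all(t in (2, 3) for t in extra) and len(extra) <= 1


# --- SAN ------------------------------------------------------------------


def san(pos: Position, move: Move) -> str:
    """Standard algebraic notation of `move` in `pos` (with +/# suffix)."""
    b = pos.board
    p = b[move.frm]
    pt = piece_type(p)
    capture = b[move.to] != EMPTY or (pt == 1 and move.to == pos.ep)
    if pt == 6 and abs(move.to - move.frm) == 2:
        core = "O-O" if move.to > move.frm else "O-O-O"
    elif pt == 1:
        core = ("abcdefgh"[move.frm % 8] + "x" if capture else "") + square_name(move.to)
        if move.promo:
            core += "=" + _PIECE_LETTER[move.promo]
    else:
        others = [
            m for m in pos.legal_moves()
            if m.to == move.to and m.frm != move.frm and piece_type(b[m.frm]) == pt
        ]
        disamb = ""
        if others:
            same_file = any(m.frm % 8 == move.frm % 8 for m in others)
            same_rank = any(m.frm // 8 == move.frm // 8 for m in others)
            if not same_file:
                disamb = "abcdefgh"[move.frm % 8]
            elif not same_rank:
                disamb = str(move.frm // 8 + 1)
            else:
                disamb = square_name(move.frm)
        core = _PIECE_LETTER[pt] + disamb + ("x" if capture else "") + square_name(move.to)
    nxt = pos.make(move)
    if nxt.in_check():
        core += "#" if nxt.is_checkmate() else "+"
    return core


_SAN_STRIP = re.compile(r"[+#!?]+$")


def parse_san(pos: Position, token: str) -> Move:
    token = _SAN_STRIP.sub("", token)
    for mv in pos.legal_moves():
        if _SAN_STRIP.sub("", san(pos, mv)) == token:
            return mv
    raise ValueError(f"illegal or unparsable SAN {token!r}")


# --- PGN ------------------------------------------------------------------

_PGN_NOISE = re.compile(r"\{[^}]*\}|\$\d+|\d+\.(\.\.)?|[()]")
_RESULTS = {"1-0", "0-1", "1/2-1/2", "*"}


def moves_to_pgn(moves: Sequence[Move], result: str = "*") -> str:
    """Render a game from the standard start as a PGN movetext block."""
    pos = Position()
    toks: list[str] = []
    for mv in moves:
        if pos.stm == WHITE:
            toks.append(f"{pos.fullmove}.")
        toks.append(san(pos, mv))
        pos = pos.make(mv)
    lines = ['[Event "?"]', '[Site "?"]', f'[Result "{result}"]', ""]
    body, line = [], ""
    for t in toks + [result]:
        if len(line) + len(t) + 1 > 79:
            body.append(line)
            line = t
        else:
            line = t if not line else line + " " + t
    body.append(line)
    return "\n".join(lines + body) + "\n"


def parse_pgn(text: str) -> list[list[Move]]:
    """Parse the movetext of one or more PGN games (headers ignored)."""
    games: list[list[Move]] = []
    chunks = re.split(r"\n\s*\n(?=\[)", text.strip())
    # fall back: treat header-free text as a single game
    for chunk in chunks:
        movetext = "\n".join(
            ln for ln in chunk.splitlines() if not ln.strip().startswith("[")
        )
        cleaned = _PGN_NOISE.sub(" ", movetext)
        toks = [t for t in cleaned.split() if t and t not in _RESULTS]
        if not toks:
            continue
        pos = Position()
        moves: list[Move] = []
        for tok in toks:
            mv = parse_san(pos, tok)
            moves.append(mv)
            pos = pos.make(mv)
        games.append(moves)
    return games


# --- independent structural legality check (test oracle) ------------------


def board_is_plausible(board: Sequence[int]) -> bool:
    """Structural sanity of a piece placement, independent of move history.

    Checks exactly one king per side, pawn counts and pawn ranks, total
    piece counts, and that the kings are not adjacent.  Used as the
    independent oracle for positions produced by the move generator.
    """
    counts = [0] * 13
    for p in board:
        counts[p] += 1
    if counts[WK] != 1 or counts[BK] != 1:
        return False
    if counts[WP] > 8 or counts[BP] > 8:
        return False
    if sum(counts[1:7]) > 16 or sum(counts[7:]) > 16:
        return False
    for sq in list(range(0, 8)) + list(range(56, 64)):
        if board[sq] in (WP, BP):
            return False
    wk, bk = board.index(WK), board.index(BK)
    if max(abs(wk % 8 - bk % 8), abs(wk // 8 - bk // 8)) <= 1:
        return False
    return True
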