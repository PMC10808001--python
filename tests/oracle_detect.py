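"""Brute-force detection oracle, independent of the library implementation.

Everything is recomputed from first principles with plain Python loops:
break positions by direct run scanning, window hydrophobic moments by
explicit trigonometric sums, arc clustering by enumerating every candidate
arc start, elements as connected components of valid-window coverage, and
the wheel-slot filter by direct counting. Used to cross-check
``detect_elements`` exhaustively on random sequences.
"""

import math


def oracle_breaks(seq, polar_set, g_run_min=2, polar_run_min=4):
    breaks = set()
    n = len(seq)
    for i, aa in enumerate(seq):
        if aa == "P":
            breaks.add(i)
    for i in range(n):
        for j in range(i, n):
            if all(seq[k] == "G" for k in range(i, j + 1)):
                if j - i + 1 >= g_run_min:
                    breaks.update(range(i, j + 1))
            else:
                break
    for i in range(n):
        for j in range(i, n):
            if all(seq[k] in polar_set for k in range(i, j + 1)):
                if j - i + 1 >= polar_run_min:
                    breaks.update(range(i, j + 1))
            else:
                break
    return breaks


def oracle_muh(seq, scale, delta_deg):
    sx = sy = 0.0
    for i, aa in enumerate(seq):
        ang = math.radians(delta_deg * i)
        sx += scale[aa] * math.cos(ang)
        sy += scale[aa] * math.sin(ang)
    return math.sqrt(sx * sx + sy * sy) / len(seq)


def oracle_arc_ok(angles, arc_max):
    """True iff some arc of width arc_max (degrees) contains every angle,
    checked by trying an arc starting at each angle."""
    if len(angles) <= 1:
        return True
    for start in angles:
        if all(((a - start) % 360.0) <= arc_max + 1e-9 for a in angles):
            return True
    return False


def oracle_window_valid(win, tables, face_min=2, face_max=5, arc_max=180.0,
                        muh_min=0.2, delta_deg=1080.0 / 11.0):
    face = [i for i, aa in enumerate(win) if aa in tables.face_set]
    if not (face_min <= len(face) <= face_max):
        return False
    angles = [(i * delta_deg) % 360.0 for i in face]
    if not oracle_arc_ok(angles, arc_max):
        return False
    return oracle_muh(win, tables.hydrophobicity, delta_deg) >= muh_min


def oracle_detect(seq, tables, muh_min=0.2, slot_filter=True):
    """Exhaustive enumeration detector; returns sorted (start, end) 1-based."""
    n = len(seq)
    breaks = oracle_breaks(seq, tables.polar_set)
    covered = set()
    for s in range(0, n - 6):
        win = seq[s : s + 7]
        if any(p in breaks for p in range(s, s + 7)):
            continue
        if oracle_window_valid(win, tables, muh_min=muh_min):
            covered.update(range(s, s + 7))
    # connected components of coverage
    elements = []
    run = []
    for p in sorted(covered) + [None]:
        if run and (p is None or p > run[-1] + 1):
            start, end = run[0], run[-1]
            sub = seq[start : end + 1]
            slots = {(3 * i) % 11 for i, aa in enumerate(sub) if aa in tables.face_set}
            if not slot_filter or 3 <= len(slots) <= 5:
                elements.append((start + 1, end + 1))
            run = []
        if p is not None:
            run.append(p)
    return elements
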