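"""Transcription of the printed 25x25 matrix of winning combinations.

Each row is a play of player B (hand, call); the value lists the plays of
player A against which B wins the round.  Rows and marks are in the
printed (hand, call) order.  This is a frozen fixture, independent of the
adjudication code it is used to check.
"""

PRINTED_B_WINS = {
    "1, 2": ("1, 3", "1, 4", "1, 5", "1, 6"),
    "1, 3": ("2, 4", "2, 5", "2, 6", "2, 7"),
    "1, 4": ("3, 5", "3, 6", "3, 7", "3, 8"),
    "1, 5": ("4, 6", "4, 7", "4, 8", "4, 9"),
    "1, 6": ("5, 7", "5, 8", "5, 9", "5, 10"),
    "2, 3": ("1, 2", "1, 4", "1, 5", "1, 6"),
    "2, 4": ("2, 3", "2, 5", "2, 6", "2, 7"),
    "2, 5": ("3, 4", "3, 6", "3, 7", "3, 8"),
    "2, 6": ("4, 5", "4, 7", "4, 8", "4, 9"),
    "2, 7": ("5, 6", "5, 8", "5, 9", "5, 10"),
    "3, 4": ("1, 2", "1, 3", "1, 5", "1, 6"),
    "3, 5": ("2, 3", "2, 4", "2, 6", "2, 7"),
    "3, 6": ("3, 4", "3, 5", "3, 7", "3, 8"),
    "3, 7": ("4, 5", "4, 6", "4, 8", "4, 9"),
    "3, 8": ("5, 6", "5, 7", "5, 9", "5, 10"),
    "4, 5": ("1, 2", "1, 3", "1, 4", "1, 6"),
    "4, 6": ("2, 3", "2, 4", "2, 5", "2, 7"),
    "4, 7": ("3, 4", "3, 5", "3, 6", "3, 8"),
    "4, 8": ("4, 5", "4, 6", "4, 7", "4, 9"),
    "4, 9": ("5, 6", "5, 7", "5, 8", "5, 10"),
    "5, 6": ("1, 2", "1, 3", "1, 4", "1, 5"),
    "5, 7": ("2, 3", "2, 4", "2, 5", "2, 6"),
    "5, 8": ("3, 4", "3, 5", "3, 6", "3, 7"),
    "5, 9": ("4, 5", "4, 6", "4, 7", "4, 8"),
    "5, 10": ("5, 6", "5, 7", "5, 8", "5, 9"),
}
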