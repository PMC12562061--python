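"""Small built-in datasets used in worked examples and validation.

``sample_sentence_conllu`` is the standard worked example for positional
dependency distance: an 11-token parse of "The young lad is going to fall
from the stool." whose published per-link distances sum to 21, giving a
sentence MDD of 21/9 = 2.33 when the punctuation link is included and the
divisor is (words - 1).

``load_function_word_metrics`` returns published node-level topology
values (betweenness C_B, closeness C_C, clustering C) for 30 shared
function-word vertices measured in an AD-group and an HC-group dependency
network built from picture-description speech.  It is the worked dataset
for the two-group comparison of network metrics.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .treebank_io import Treebank, read_conllu_text

__all__ = [
    "sample_sentence_conllu",
    "sample_sentence_treebank",
    "load_function_word_metrics",
]

_SAMPLE_CONLLU = """\
# sent_id = sample-1
1\tThe\t_\tDT\t_\t_\t3\tdet\t_\t_
2\tyoung\t_\tJJ\t_\t_\t3\tamod\t_\t_
3\tlad\t_\tNN\t_\t_\t5\tnsubj\t_\t_
4\tis\t_\tVBZ\t_\t_\t5\taux\t_\t_
5\tgoing\t_\tVBG\t_\t_\t0\troot\t_\t_
6\tto\t_\tTO\t_\t_\t7\tmark\t_\t_
7\tfall\t_\tVB\t_\t_\t5\txcomp\t_\t_
8\tfrom\t_\tIN\t_\t_\t10\tcase\t_\t_
9\tthe\t_\tDT\t_\t_\t10\tdet\t_\t_
10\tstool\t_\tNN\t_\t_\t7\tobl\t_\t_
11\t.\t_\tPUNCT\t_\t_\t5\tpunct\t_\t_
"""


def sample_sentence_conllu() -> str:
    """CoNLL-U text of the worked-example sentence."""
    return _SAMPLE_CONLLU


def sample_sentence_treebank() -> Treebank:
    """The worked-example sentence as a one-sentence treebank."""
    return read_conllu_text(_SAMPLE_CONLLU, group_label="sample",
                            source="sample_sentence")


# 30 function-word vertices x (C_B, C_C, C) in the AD and HC networks.
_FUNCTION_WORD_METRICS_CSV = """\
vertex,cb_ad,cc_ad,c_ad,cb_hc,cc_hc,c_hc
there,0.022099,0.457022,0.121477,0.013476,0.414263,0.127551
you,0.009195,0.37477,0.060256,0.006968,0.343243,0.012315
so,0.003254,0.393383,0.141129,0.004128,0.372544,0.060504
this,0.03203,0.452823,0.080184,0.001157,0.394093,0.156085
here,0.022918,0.456552,0.120702,0.002895,0.391002,0.231579
whether,0.000529,0.331495,0.066667,0.000059,0.308672,0
from,0.003303,0.396018,0.157143,0.000227,0.341141,0.004762
down,0.006221,0.409358,0.123113,0.000378,0.341264,0.011696
may,0.003326,0.305573,1,0.000024,0.328479,0.166667
must,0.000249,0.338064,0.145455,0.000011,0.302655,0
was,0.008557,0.410305,0.107692,0.001198,0.383714,0.115942
should,0.000078,0.326492,0,0.000029,0.296495,0
where,0.001342,0.400126,0.205882,0.004412,0.378651,0.084967
some,0.011713,0.412212,0.1,0.004527,0.349707,0.054348
did,0.001305,0.408981,0.263158,0.00131,0.321128,0
onto,0.000019,0.344765,0.5,0.000013,0.302075,0
does,0.000006,0.362814,0.4,0.000007,0.31389,0
then,0.000542,0.397081,0.171429,0.000177,0.340527,0.051282
sometimes,0,0.316588,0,0,0.247907,0
very,0.008912,0.322574,0.012821,0.002228,0.282688,0
mostly,0,0.320941,0,0.000087,0.27011,0
after,0.002219,0.375563,0.333333,0.000001,0.311515,0
my,0.002512,0.336015,0.054545,0.000029,0.277714,0
those,0.000325,0.353418,0.285714,0.000006,0.291028,0
someone,0.000006,0.331495,0.2,0,0.262111,0
could,0.000247,0.371163,0.181818,0.000247,0.329738,0
pretty,0.003071,0.351319,0.133333,0.002493,0.315039,0
through,0.000473,0.354974,0.075758,0.000001,0.308572,0
neither,0,0.299993,0,0,0.22225,0
unless,0,0.290465,0,0,0.210821,0
"""


def load_function_word_metrics() -> pd.DataFrame:
    """Published function-word network metrics, indexed by vertex.

    Columns ``cb_ad``, ``cc_ad``, ``c_ad`` hold betweenness, closeness and
    clustering in the AD-group network; ``*_hc`` likewise for the HC
    network.  30 rows, one per shared function-word vertex.
    """
    return pd.read_csv(StringIO(_FUNCTION_WORD_METRICS_CSV), index_col="vertex")
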