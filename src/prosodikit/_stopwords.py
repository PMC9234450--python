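"""Default stoplist of overly common English function words.

Collocate extraction filters these out so that frequency-ranked collocate
lists are not dominated by determiners, prepositions, pronouns, auxiliaries
and other closed-class items. The list is deliberately plain and
user-replaceable: pass any iterable of words as ``CollocationConfig.stoplist``
to override it.
"""

DEFAULT_STOPLIST = frozenset("""
a an the this that these those some any each every either neither no
i you he she it we they me him her us them my your his its our their
mine yours hers ours theirs myself yourself himself herself itself
ourselves yourselves themselves who whom whose which what
and or but nor so yet for because although though while whereas if
unless until since when whenever where wherever whether than as
in on at by with from into onto of to about above below under over
between among through during before after against without within
along across behind beyond up down off out near upon toward towards
be am is are was were been being
have has had having
do does did doing done
will would shall should can could may might must ought
not never also just only very too quite rather
there here now then once again further more most less least
such same other another both all many much few little
own else ever even still yes
one two three first second new old
get gets got getting go goes went going gone
say says said make makes made
s t re ve ll d m don isn aren wasn weren hasn haven hadn doesn didn
won wouldn shouldn couldn mustn
""".split())
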