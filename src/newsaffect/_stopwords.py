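"""Default English stop-word list.

A standard list of high-frequency English function words (pronouns, articles,
auxiliaries, prepositions, conjunctions). Users can extend it with a plain-text
additions file (one word per line) to cover domain noise such as place names,
media boilerplate, or proper nouns that collide with lexicon entries.
"""

ENGLISH_STOPWORDS = frozenset(
    """
a about above after again against all am an and any are aren arent as at be
because been before being below between both but by can cannot could couldnt
did didn didnt do does doesn doesnt doing don dont down during each few for
from further had hadn hadnt has hasn hasnt have haven havent having he hed
hell her here hers herself hes him himself his how hows i id if ill im in into
is isn isnt it its itself ive just let lets me more most mustn mustnt my
myself no nor not now of off on once only or other ought our ours ourselves
out over own re s same shan shant she shed shell shes should shouldn shouldnt
so some such t than that thats the their theirs them themselves then there
theres these they theyd theyll theyre theyve this those through to too under
until up ve very was wasn wasnt we wed well were weren werent weve what whats
when whens where wheres which while who whom whos why whys will with won wont
would wouldn wouldnt you youd youll your youre yours yourself yourselves youve
""".split()
)
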