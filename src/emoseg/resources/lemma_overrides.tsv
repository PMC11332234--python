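# Derivational merge table: surface form -> canonical lemma.
# Inflectional variants are handled by suffix rules; this table collapses
# derivational pairs (adjective/noun/adverb) that share an emotion concept,
# e.g. "angry" and "anger" count as one label. Tab-separated; edit freely.
angry	anger
angrily	anger
angered	anger
angering	anger
enraged	rage
raging	rage
furious	fury
furiously	fury
annoyed	annoyance
annoying	annoyance
annoy	annoyance
frustrated	frustration
frustrating	frustration
frustrate	frustration
irritated	irritation
irritating	irritation
irritate	irritation
resentful	resentment
resent	resentment
outraged	outrage
hostile	hostility
exasperated	exasperation
disgusted	disgust
disgusting	disgust
revolted	revulsion
contemptuous	contempt
loathe	loathing
loathed	loathing
repulsed	repulsion
averse	aversion
scornful	scorn
disdainful	disdain
nauseated	nausea
nauseous	nausea
fearful	fear
feared	fear
afraid	fear
scared	fear
scary	fear
anxious	anxiety
terrified	terror
terrifying	terror
dreadful	dread
dreaded	dread
panicked	panic
panicky	panic
worried	worry
worrying	worry
apprehensive	apprehension
uneasy	unease
frightened	fright
frightening	fright
alarmed	alarm
happy	happiness
happily	happiness
joyful	joy
joyous	joy
delighted	delight
delightful	delight
amused	amusement
amusing	amusement
excited	excitement
exciting	excitement
content	contentment
contented	contentment
proud	pride
relieved	relief
affectionate	affection
pleased	pleasure
pleasant	pleasure
sad	sadness
sadly	sadness
saddened	sadness
grieving	grief
grieved	grief
sorrowful	sorrow
disappointed	disappointment
disappointing	disappointment
despairing	despair
desperate	despair
miserable	misery
lonely	loneliness
gloomy	gloom
regretful	regret
regretted	regret
hurtful	hurt
surprised	surprise
surprising	surprise
shocked	shock
shocking	shock
astonished	astonishment
astonishing	astonishment
amazed	amazement
amazing	amazement
confused	confusion
confusing	confusion
incredulous	disbelief
wondrous	wonder
bewildered	bewilderment
bewildering	bewilderment
startled	startle
startling	startle
awed	awe
awestruck	awe
upset	upset
jealous	jealousy
envious	envy
ashamed	shame
embarrassed	embarrassment
embarrassing	embarrassment
guilty	guilt
hopeful	hope
hopeless	hopelessness
bored	boredom
boring	boredom
calm	calm
calmness	calm
nervous	nervousness
tense	tension
stressed	stress
stressful	stress
loving	love
loved	love
hateful	hate
hated	hate
hatred	hate
curious	curiosity
sympathetic	sympathy
empathetic	empathy
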