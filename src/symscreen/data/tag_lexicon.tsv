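often	RB
fails	VBZ
fail	VB
give	VB
gives	VBZ
close	JJ
attention	NN
detail	NN
details	NNS
makes	VBZ
make	VB
careless	JJ
mistake	NN
mistakes	NNS
difficulty	NN
sustaining	VBG
sustain	VB
task	NN
tasks	NNS
play	VB
plays	VBZ
activity	NN
activities	NNS
seems	VBZ
seem	VB
listen	VB
listens	VBZ
spoken	VBN
speak	VB
speaks	VBZ
directly	RB
follow	VB
follows	VBZ
through	IN
instruction	NN
instructions	NNS
finish	VB
finishes	VBZ
organizing	VBG
organize	VB
organizes	VBZ
avoid	VB
avoids	VBZ
reluctant	JJ
engage	VB
engages	VBZ
required	VBD
require	VB
requires	VBZ
mental	JJ
effort	NN
loses	VBZ
lose	VB
thing	NN
things	NNS
necessary	JJ
easily	RB
distracted	VBN
distract	VB
distracts	VBZ
extraneous	JJ
stimuli	NNS
stimulus	NN
forgetful	JJ
forget	VB
forgets	VBZ
daily	JJ
fidgets	VBZ
fidget	VB
taps	VBZ
tap	VB
hand	NN
hands	NNS
foot	NN
feet	NNS
squirms	VBZ
squirm	VB
seat	NN
leaves	VBZ
leave	VB
situation	NN
situations	NNS
remaining	VBG
remain	VB
remains	VBZ
seated	VBN
sit	VB
sits	VBZ
excepted	VBN
expected	VBN
expect	VB
except	VB
runs	VBZ
run	VB
about	RB
climb	VB
climbs	VBZ
inappropriate	JJ
unable	JJ
leisure	NN
quietly	RB
go	VB
goes	VBZ
acting	VBG
act	VB
acts	VBZ
driven	VBN
drive	VB
drives	VBZ
motor	NN
talks	VBZ
talk	VB
excessively	RB
blurts	VBZ
blurt	VB
out	RP
answer	NN
answers	NNS
question	NN
questions	NNS
completed	VBN
complete	VB
waiting	VBG
wait	VB
waits	VBZ
turn	NN
turns	NNS
interrupts	VBZ
interrupt	VB
intrudes	VBZ
intrude	VB
other	JJ
others	NNS
chore	NN
chores	NNS
error	NN
errors	NNS
item	NN
items	NNS
chair	NN
frequently	RB
focus	NN
trouble	NN
duty	NN
duties	NNS
game	NN
games	NNS
work	NN
arrange	VB
arranges	VBZ
misplace	VB
misplaces	VBZ
remember	VB
remembers	VBZ
chatter	VB
chatters	VBZ
reply	NN
replies	NNS
query	NN
argues	VBZ
argue	VB
adult	NN
adults	NNS
refuses	VBZ
refuse	VB
comply	VB
complies	VBZ
request	NN
requests	NNS
sad	JJ
empty	JJ
hopeless	JJ
day	NN
days	NNS
deliberately	RB
annoys	VBZ
annoy	VB
people	NNS
person	NN
interest	NN
pleasure	NN
mood	NN
irritable	JJ
angry	JJ
resentful	JJ
blames	VBZ
blame	VB
rule	NN
rules	NNS
defies	VBZ
defy	VB
actively	RB
spiteful	JJ
vindictive	JJ
cruel	JJ
bullies	VBZ
bully	VB
threatens	VBZ
threaten	VB
intimidates	VBZ
intimidate	VB
fight	NN
fights	NNS
destroys	VBZ
destroy	VB
property	NN
lies	VBZ
lie	VB
obtain	VB
obtains	VBZ
favor	NN
favors	NNS
obligation	NN
obligations	NNS
sleeps	VBZ
sleep	VB
feels	VBZ
feel	VB
worthless	JJ
guilt	NN
fatigue	NN
energy	NN
appetite	NN
school	NN
home	NN
night	NN
little	JJ
much	JJ
starts	VBZ
start	VB
cries	VBZ
cry	VB
tearful	JJ
complains	VBZ
complain	VB
ache	NN
aches	NNS
headache	NN
headaches	NNS
stomach	NN
concentrate	VB
concentrates	VBZ
withdrawn	JJ
friend	NN
friends	NNS
toy	NN
toys	NNS
breaks	VBZ
break	VB
belongings	NNS
tantrum	NN
tantrums	NNS
temper	NN
hits	VBZ
hit	VB
kicks	VBZ
kick	VB
bites	VBZ
bite	VB
slow	JJ
tired	JJ
moves	VBZ
move	VB
ran	VBD
made	VBD
lost	VBD
left	VBD
gave	VBD
went	VBD
sat	VBD
spoke	VBD
drove	VBD
forgot	VBD
kept	VBD
felt	VBD
thought	VBD
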