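diaper	nappy
diapers	nappies
mom	mum
moms	mums
pacifier	dummy
pacifiers	dummies
stroller	buggy
strollers	buggies
crib	cot
cribs	cots
color	colour
colors	colours
colored	coloured
behavior	behaviour
behaviors	behaviours
favorite	favourite
favorites	favourites
center	centre
centers	centres
theater	theatre
gray	grey
math	maths
candy	sweets
trash	rubbish
garbage	rubbish
vacation	holiday
vacations	holidays
soccer	football
cookie	biscuit
cookies	biscuits
apartment	flat
sidewalk	pavement
faucet	tap
closet	wardrobe
restroom	toilet
elevator	lift
flashlight	torch
pants	trousers
sneakers	trainers
sweater	jumper
realize	realise
realized	realised
realizing	realising
recognize	recognise
recognized	recognised
organize	organise
organized	organised
apologize	apologise
neighbor	neighbour
neighbors	neighbours
neighborhood	neighbourhood
labor	labour
flavor	flavour
humor	humour
rumor	rumour
pediatrician	paediatrician
pediatric	paediatric
counselor	counsellor
traveling	travelling
canceled	cancelled
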