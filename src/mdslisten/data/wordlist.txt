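the 5000
and 4500
to 4200
of 4000
a 3900
i 3800
in 3500
it 3300
is 3200
was 3100
my 3000
for 2900
that 2800
with 2700
he 2600
she 2600
her 2500
his 2500
on 2400
at 2300
we 2200
this 2100
but 2000
had 1900
have 1900
has 1800
are 1700
be 1700
not 1600
been 1500
so 1400
they 1400
all 1300
me 1300
when 1200
out 1100
up 1100
about 1000
what 1000
just 950
know 900
time 900
get 850
like 850
after 800
now 800
week 780
weeks 770
month 760
months 750
year 740
years 730
today 720
doctor 700
doctors 690
hospital 680
blood 670
counts 660
count 650
marrow 640
bone 630
results 620
test 610
tests 600
feeling 590
feel 580
felt 570
tired 560
fatigue 550
treatment 540
treatments 530
transfusion 520
transfusions 510
transplant 500
donor 490
cells 480
stem 470
chemo 460
chemotherapy 450
cycle 440
cycles 430
started 420
start 410
going 400
went 390
back 380
home 370
family 360
husband 350
wife 340
mother 330
father 320
care 310
caring 300
caregiver 290
patient 280
patients 270
nurse 260
appointment 250
appointments 240
clinic 230
visit 220
last 210
next 200
still 195
very 190
much 185
good 180
better 175
worse 170
hard 165
day 160
days 155
night 150
morning 145
told 140
said 135
asked 130
waiting 125
wait 120
news 115
hope 110
hoping 105
thanks 100
thank 98
everyone 96
anyone 94
here 92
there 90
will 88
would 86
could 84
should 82
need 80
needs 78
help 76
question 74
questions 72
new 70
first 68
second 66
since 64
because 62
really 60
little 58
lot 56
well 54
also 52
from 50
them 50
receive 48
received 46
give 44
gave 42
keep 40
keeps 38
take 36
taking 34
took 32
make 30
made 28
find 26
found 24
read 22
reading 20
post 19
posts 18
forum 17
share 16
sharing 15
story 14
journey 13
diagnosed 12
diagnosis 12
mds 11
myelodysplastic 11
syndrome 11
syndromes 11
aml 10
anemia 10
blast 10
blasts 10
hemoglobin 10
leukemia 10
neutrophils 10
platelets 10
azacitidine 9
decitabine 9
erythropoietin 9
hematologist 9
infusion 9
injections 9
oncologist 9
regimen 9
specialist 9
venetoclax 9
advancing 8
biopsy 8
copay 8
cytogenetics 8
insurance 8
monitoring 8
paperwork 8
parking 8
prognosis 8
progression 8
referral 8
scheduling 8
appetite 7
complications 7
conditioning 7
diet 7
encouragement 7
engraftment 7
exercise 7
graft 7
hospitalized 7
hugs 7
infection 7
lifestyle 7
nausea 7
nutrition 7
pain 7
pneumonia 7
support 7
symptoms 7
anniversary 6
birthday 6
burden 6
choose 6
decide 6
decision 6
energy 6
exhausting 6
findings 6
graduation 6
grandchild 6
independence 6
levels 6
life 6
milestone 6
option 6
options 6
quality 6
research 6
struggle 6
studies 6
toll 6
wedding 6
weighing 6
afraid 5
anxious 5
clinical 5
concerned 5
confused 5
explain 5
explained 5
frustrated 5
grateful 5
happy 5
hopeful 5
information 5
learn 5
resources 5
sad 5
scared 5
trial 5
trials 5
understand 5
worried 5
abbvie 2
according 2
activities 2
adams 2
added 2
advice 2
again 2
agent 2
agios 2
alice 2
allen 2
allogeneic 2
am 2
an 2
anderson 2
angry 2
announced 2
another 2
anxiety 2
any 2
apprehensive 2
area 2
article 2
astellas 2
astonished 2
baffled 2
baker 2
barbara 2
barry 2
becky 2
best 2
between 2
bluebird 2
bortezomib 2
brian 2
bristol 2
brother 2
brown 2
by 2
call 2
called 2
calm 2
came 2
can 2
canada 2
cancer 2
carol 2
caught 2
cbc 2
celebrating 2
celgene 2
cell 2
charles 2
checked 2
checking 2
clark 2
cleveland 2
clofarabine 2
clolar 2
com 2
coming 2
concerning 2
confusing 2
continue 2
conversation 2
covers 2
dad 2
daily 2
dana 2
daniel 2
data 2
daughter 2
daurismo 2
david 2
davis 2
dealing 2
decided 2
delighted 2
describes 2
details 2
devastated 2
developed 2
diagnostic 2
did 2
disease 2
disgusted 2
dli 2
does 2
donna 2
dr 2
dreading 2
drive 2
drug 2
edge 2
effects 2
emily 2
emma 2
enasidenib 2
encouraged 2
epo 2
everyday 2
example 2
exasperated 2
experience 2
factors 2
failed 2
farber 2
fed 2
feels 2
forward 2
frank 2
fred 2
frequent 2
fretting 2
friday 2
frightened 2
frustrating 2
furious 2
garcia 2
gardener 2
gemtuzumab 2
genentech 2
george 2
getting 2
gilteritinib 2
glasdegib 2
gloria 2
goes 2
grandfather 2
grandmother 2
green 2
grieving 2
group 2
growth 2
guard 2
hall 2
haploidentical 2
harbor 2
harris 2
health 2
heartbroken 2
helen 2
hello 2
hematopoietic 2
high 2
higher 2
holly 2
honest 2
hopkins 2
how 2
hutchinson 2
hypomethylating 2
idhifa 2
if 2
imetelstat 2
induction 2
infuriating 2
institute 2
intensive 2
intermediate 2
into 2
iron 2
ivosidenib 2
jackson 2
james 2
jane 2
jazz 2
joan 2
john 2
johns 2
johnson 2
jones 2
joseph 2
joyful 2
karen 2
kettering 2
kind 2
king 2
kingdom 2
lack 2
lantern 2
lately 2
latest 2
laura 2
lewis 2
linda 2
listening 2
livid 2
living 2
logistics 2
long 2
looking 2
love 2
low 2
lymphocyte 2
magrolimab 2
makes 2
maria 2
mark 2
martin 2
martinez 2
mary 2
mayo 2
md 2
meadow 2
mean 2
means 2
memorial 2
met 2
michael 2
miller 2
mom 2
monday 2
monthly 2
moore 2
more 2
mostly 2
mountain 2
mourning 2
multiple 2
myers 2
mylotarg 2
nancy 2
national 2
nauseating 2
nci 2
neutropenia 2
no 2
nobody 2
novartis 2
off 2
one 2
ongoing 2
opinion 2
optimistic 2
osuccc 2
other 2
otsuka 2
our 2
outraged 2
overjoyed 2
overload 2
ozogamicin 2
panicking 2
partner 2
patricia 2
paul 2
pevonedistat 2
pfizer 2
pharmaceuticals 2
pharmacist 2
pine 2
plan 2
planned 2
please 2
pocket 2
posting 2
preparing 2
press 2
process 2
progressed 2
put 2
puts 2
quick 2
quilter 2
reader 2
recommended 2
regular 2
release 2
repulsed 2
researchers 2
responding 2
revolting 2
richard 2
ride 2
rising 2
risk 2
robert 2
rodriguez 2
room 2
runner 2
ruth 2
ryan 2
sabatolimab 2
sailor 2
sanofi 2
sarah 2
say 2
schedule 2
scheduled 2
score 2
scott 2
seastar 2
sending 2
sense 2
shocked 2
short 2
side 2
sister 2
sloan 2
smith 2
son 2
soon 2
sorrowful 2
sparrow 2
spent 2
squibb 2
stand 2
states 2
stay 2
steven 2
stopped 2
strong 2
stunned 2
suffer 2
suffers 2
susan 2
switching 2
system 2
takeda 2
talked 2
tamibarotene 2
taylor 2
team 2
tearful 2
tell 2
terrified 2
therapy 2
things 2
thinking 2
thompson 2
thrilled 2
tibsovo 2
transformed 2
transplantation 2
travel 2
tried 2
troubling 2
tuesday 2
turned 2
understanding 2
uneasy 2
unexpected 2
united 2
unmet 2
update 2
us 2
velcade 2
venclexta 2
version 2
walker 2
weekly 2
weighs 2
where 2
which 2
while 2
white 2
williams 2
willow 2
wilson 2
wish 2
wishing 2
wonderful 2
word 2
working 2
write 2
writing 2
xospata 2
you 2
young 2
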