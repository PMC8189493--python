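a
abolished
about
above
acquired
across
adjacent
affinity
after
again
against
all
allows
almost
along
also
although
always
am
among
an
analysis
and
animal
animals
another
anti-
antibodies
antibody
antigens
any
anyone
anything
approach
are
area
areas
around
array
arrays
as
assay
assays
assess
assessed
assessment
at
available
average
away
back
background
band
bands
base
based
basic
be
became
because
become
becomes
been
before
began
begin
behind
being
below
between
binding
bindwell
biological
blocked
blocking
blood
blot
blots
body
both
brain
buffer
buffered
but
by
came
can
cannot
case
cases
cat
catalog
cause
caveat
cell
cells
certain
change
changes
chemical
clear
clearly
clinical
clonarta
clone
colorimetric
come
comes
common
commonly
compared
comparison
comparisons
completely
compound
concentration
concentrations
condition
conditions
confirm
confirmed
confirming
confocal
considerable
constant
contaminating
control
controls
corresponding
could
cross-reactive
cross-reactivity
culture
cycle
data
day
days
degree
degrees
demonstrate
density
described
design
designed
detect
detected
detection
determine
determined
development
did
difference
differences
different
direct
directly
disease
do
does
done
dose
double
down
during
each
early
effect
effects
either
embedded
end
enough
entire
enzyme
enzyme-linked
enzymes
evaluated
even
ever
every
evidence
example
except
expected
experiment
experimental
experiments
exposed
expressed
expression
factor
factors
far
few
figure
figures
film
final
finally
first
five
fixed
fluorescence
followed
following
food
for
form
found
four
free
frequency
from
function
further
gain
gave
gene
general
genes
get
give
given
goes
good
got
great
group
growth
had
has
have
having
he
health
her
here
high
higher
highest
highly
him
his
hoc
housed
how
however
human
humans
hundred
i
if
image
images
imaging
immunizing
immunoblot
immunoblots
immunoblotting
immunolabeling
immunoprecipitation
immunora
immunoreactivity
immunosorbent
immunostaining
important
in
include
included
including
increase
increased
incubated
incubation
indeed
independent
indicate
indicated
individual
individuals
induced
information
instead
intensities
intensity
interaction
interactions
into
is
isoform
isoforms
it
its
itself
just
keep
kept
kinase
knockout
known
label
labeled
labeling
laboratory
lack
lacking
large
last
later
least
left
length
less
let
level
levels
light
like
likely
line
lines
little
localization
long
low
lower
lysate
lysates
made
main
major
make
makes
male
many
mass
material
materials
matrix
may
mean
means
measure
measured
measurement
measurements
mechanism
media
medium
membrane
membranes
method
methods
mice
microscope
microscopy
might
minute
minutes
mixture
model
models
molecular
monoclonal
more
most
mouse
much
must
mutant
mutants
near
nearly
need
needed
negative
never
new
next
nine
no
non-specific
none
nonspecific
nor
normal
not
note
noted
novagenix
now
nuclear
null
number
observed
obtained
occur
occurred
of
off
often
old
older
omitting
on
once
one
only
open
or
order
other
others
our
out
over
overnight
own
paraffin
paraformaldehyde
parallel
part
particular
parts
pathway
pathways
patient
patients
peptide
peptides
per
performed
perhaps
persisted
phosphate
picture
place
placed
point
points
polyclonal
population
positive
possible
post
potential
pre-cleared
presence
present
presented
pressure
previous
previously
primary
primer
primers
prior
probably
probed
probing
procedure
procedures
process
produced
products
protein
proteins
protheon
protocol
provide
provided
published
purchased
purified
put
quantification
quantified
rabbit
range
rat
rather
ratio
rats
reaction
reactions
reagent
reagents
recent
recently
receptor
receptors
recombinant
reduced
reflect
region
regions
related
relative
remained
remains
remove
removed
repeated
report
reported
respectively
response
responses
result
resulting
results
room
saline
same
sample
samples
saw
say
scale
science
scientific
second
seconds
section
sections
see
seem
seen
sequence
sequences
series
serum
set
seven
several
shall
she
should
show
showed
shown
shows
signal
signals
significant
significantly
similar
simple
since
site
sites
six
small
so
software
some
something
sometimes
source
species
specific
specificity
stained
staining
standard
state
stated
states
statistical
still
strain
strains
structure
structures
study
subject
subjects
substantial
such
suggest
suggested
suggesting
supernatant
surface
system
systems
take
taken
target
targets
technique
techniques
temperature
ten
test
tested
testing
tests
than
that
the
their
them
then
theory
therapy
there
therefore
these
they
third
this
those
though
three
through
thus
time
times
tissue
tissues
to
together
too
total
toward
treated
treatment
treatments
trial
two
type
types
under
unknown
unrelated
until
up
upon
use
used
uses
using
usually
value
values
variance
various
very
vitro
vivo
volume
was
washed
water
way
we
weight
well
were
western
what
when
where
whereas
whether
which
while
who
whole
whose
why
wild
wild-type
will
with
within
without
work
would
year
years
yet
you
your
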