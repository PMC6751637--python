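# Default term-refinement stoplist: surface forms that collide with common
# English words or geographic names and must never enter a dictionary.
# One entry per line; matching is case-insensitive after whitespace
# normalization; "#" starts a comment.

# --- common English function/content words ---
a
about
above
after
again
against
all
also
among
an
and
any
are
around
as
at
bat
be
because
been
before
being
below
between
both
but
by
can
cane
could
did
do
does
doing
down
during
each
few
for
from
further
had
has
have
having
he
her
here
hers
him
his
how
if
in
into
is
it
its
itself
just
may
me
more
most
my
new
no
nor
not
now
of
off
on
once
only
or
other
our
ours
out
over
own
rat
same
she
should
so
some
such
than
that
the
their
theirs
them
then
there
these
they
this
those
through
to
too
under
until
up
very
was
we
were
what
when
where
which
while
who
whom
why
will
with
would
you
your
yours

# --- common biomedical/report words ambiguous with taxon or disease names ---
agent
cell
chest
cold
common
complex
data
group
major
minor
patient
patients
right
serum
spot
this study
type
water

# --- geographic names observed as spurious pathogen hits ---
africa
america
arabia
asia
australia
china
congo
europe
india
japan
katanga
kenya
mexico
nigeria
pakistan
peru
sudan
uganda
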