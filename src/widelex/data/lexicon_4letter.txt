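TORE
WEND
BOOR
TARE
KRIS
ABLE
ACHE
ACID
ACRE
AGED
AKIN
ALSO
AREA
ARMY
AUNT
AWAY
BABY
BACK
BAIT
BAKE
BALD
BALL
BAND
BANK
BARE
BARK
BARN
BASE
BATH
BEAD
BEAK
BEAM
BEAN
BEAR
BEAT
BEEF
BEEN
BEER
BELL
BELT
BEND
BENT
BEST
BIKE
BILL
BIND
BIRD
BITE
BLEW
BLOW
BLUE
BOAR
BOAT
BODY
BOIL
BOLD
BOLT
BOMB
BOND
BONE
BOOK
BOOM
BOOT
BORE
BORN
BOTH
BOWL
BRAG
BRAN
BRIM
BUCK
BULK
BULL
BUMP
BURN
BURY
BUSH
BUSY
CAFE
CAGE
CAKE
CALF
CALL
CALM
CAME
CAMP
CANE
CAPE
CARD
CARE
CART
CASE
CASH
CAST
CAVE
CELL
CENT
CHAT
CHEF
CHEW
CHIN
CHIP
CHOP
CITE
CITY
CLAD
CLAN
CLAP
CLAW
CLAY
CLIP
CLUB
CLUE
COAL
COAT
CODE
COIL
COIN
COLD
COMB
COME
COOK
COOL
COPE
COPY
CORD
CORE
CORK
CORN
COST
COVE
COZY
CRAB
CREW
CRIB
CROP
CROW
CUBE
CULT
CURB
CURE
CURL
CUTE
DAME
DAMP
DARE
DARK
DART
DASH
DATE
DAWN
DAYS
DEAF
DEAL
DEAN
DEAR
DEBT
DECK
DEED
DEEP
DEER
DENT
DENY
DESK
DIAL
DICE
DIET
DINE
DIRT
DISH
DIVE
DOCK
DOES
DOLL
DOME
DONE
DOOM
DOOR
DOSE
DOVE
DOWN
DRAG
DRAW
DREW
DRIP
DROP
DRUM
DUCK
DUEL
DUET
DULL
DUMP
DUSK
DUST
DUTY
EACH
EARL
EARN
EASE
EAST
EASY
ECHO
EDGE
EDIT
ELSE
EPIC
EVEN
EVER
EVIL
EXAM
EXIT
FACE
FACT
FADE
FAIL
FAIR
FAKE
FALL
FAME
FARE
FARM
FAST
FATE
FAWN
FEAR
FEAT
FEED
FEEL
FEET
FELL
FELT
FERN
FILE
FILL
FILM
FIND
FINE
FIRE
FIRM
FISH
FIST
FIVE
FLAG
FLAP
FLAT
FLAW
FLED
FLEW
FLIP
FLOW
FOAM
FOIL
FOLD
FOLK
FOND
FONT
FOOD
FOOT
FORD
FORK
FORM
FORT
FOUL
FOUR
FOWL
FREE
FROG
FROM
FUEL
FULL
FUND
FURY
FUSE
GAIN
GAIT
GALE
GAME
GANG
GATE
GAVE
GAZE
GEAR
GIFT
GIRL
GIVE
GLAD
GLEN
GLOW
GLUE
GOAL
GOAT
GOES
GOLD
GOLF
GONE
GOOD
GOWN
GRAB
GRAM
GRAY
GREW
GRID
GRIM
GRIN
GRIP
GROW
GULF
GUSH
HAIL
HAIR
HALF
HALL
HALT
HAND
HANG
HARD
HARE
HARM
HARP
HATE
HAUL
HAVE
HAWK
HAZE
HEAD
HEAL
HEAP
HEAR
HEAT
HEEL
HEIR
HELD
HELM
HELP
HERB
HERD
HERE
HERO
HIDE
HIGH
HIKE
HILL
HINT
HIRE
HOLD
HOLE
HOLY
HOME
HOOD
HOOF
HOOK
HOPE
HORN
HOSE
HOST
HOUR
HUGE
HUNT
HURL
HURT
HUSH
ICON
IDEA
IDLE
INCH
INTO
IRON
ITEM
JADE
JAZZ
JOIN
JOKE
JOLT
JURY
JUST
KEEN
KEEP
KEPT
KICK
KIND
KING
KISS
KITE
KNEE
KNEW
KNIT
KNOB
KNOT
KNOW
LACE
LACK
LAID
LAKE
LAMB
LAMP
LAND
LANE
LAST
LATE
LAVA
LAWN
LAZY
LEAD
LEAF
LEAN
LEAP
LEFT
LEND
LENS
LESS
LIFE
LIFT
LIKE
LIMB
LIME
LINE
LINK
LION
LIST
LIVE
LOAD
LOAF
LOAN
LOCK
LOFT
LOGO
LONE
LONG
LOOK
LOOM
LOOP
LORD
LOSE
LOSS
LOST
LOUD
LOVE
LUCK
LUMP
LUNG
LURE
LUSH
MADE
MAID
MAIL
MAIN
MAKE
MALE
MALT
MANY
MAPS
MARE
MARK
MASK
MAST
MATE
MAZE
MEAL
MEAN
MEAT
MEEK
MEET
MELT
MEND
MENU
MESH
MESS
MILD
MILE
MILK
MILL
MIND
MINE
MINT
MIST
MOAT
MODE
MOLD
MOLE
MONK
MOOD
MOON
MORE
MOSS
MOST
MOTH
MOVE
MUCH
MULE
MUST
MUTE
MYTH
NAIL
NAME
NAVY
NEAR
NEAT
NECK
NEED
NEST
NEWS
NEXT
NICE
NINE
NODE
NONE
NOON
NORM
NOSE
NOTE
NOUN
OATH
OBEY
ODDS
ONCE
ONLY
ONTO
OPEN
ORAL
OVAL
OVEN
OVER
PACE
PACK
PAGE
PAID
PAIL
PAIN
PAIR
PALE
PALM
PANE
PARK
PART
PASS
PAST
PATH
PAVE
PAWN
PEAK
PEAR
PEAT
PECK
PEEL
PEER
PELT
PERK
PEST
PICK
PIER
PILE
PILL
PINE
PINK
PINT
PIPE
PLAN
PLAY
PLEA
PLOT
PLOW
PLUG
PLUM
PLUS
POEM
POET
POLE
POLL
POND
PONY
POOL
POOR
PORE
PORK
PORT
POSE
POST
POUR
PRAY
PREY
PROP
PULL
PUMP
PURE
PUSH
QUIT
QUIZ
RACE
RACK
RAFT
RAGE
RAID
RAIL
RAIN
RAKE
RAMP
RANG
RANK
RARE
RASH
RATE
RAVE
READ
REAL
REAP
REAR
REED
REEF
REEL
RELY
RENT
REST
RICE
RICH
RIDE
RIND
RING
RIPE
RISE
RISK
ROAD
ROAM
ROAR
ROBE
ROCK
RODE
ROLE
ROLL
ROOF
ROOM
ROOT
ROPE
ROSE
RUDE
RUIN
RULE
RUNG
RUSH
RUST
SAFE
SAGE
SAID
SAIL
SAKE
SALE
SALT
SAME
SAND
SANE
SANG
SANK
SAVE
SCAN
SCAR
SEAL
SEAM
SEAT
SEED
SEEK
SEEM
SEEN
SELF
SELL
SEND
SENT
SHED
SHIP
SHOE
SHOP
SHOT
SHOW
SHUT
SICK
SIDE
SIGH
SIGN
SILK
SING
SINK
SITE
SIZE
SKIN
SKIP
SLAB
SLAM
SLED
SLIM
SLIP
SLOW
SNAP
SNOW
SOAK
SOAP
SOAR
SOCK
SOFA
SOFT
SOIL
SOLD
SOLE
SOME
SONG
SOON
SORE
SORT
SOUL
SOUP
SOUR
SPAN
SPIN
SPOT
SPUN
STAB
STAR
STAY
STEM
STEP
STIR
STOP
STOW
SUCH
SUIT
SUNG
SURE
SWAM
SWAN
SWAP
SWAY
SWIM
TACK
TAIL
TAKE
TALE
TALK
TALL
TAME
TANK
TAPE
TASK
TEAM
TEAR
TELL
TEND
TENT
TERM
TEST
TEXT
THAN
THAT
THAW
THEM
THEN
THEY
THIN
THIS
THUS
TIDE
TIDY
TILE
TILL
TILT
TIME
TINY
TIRE
TOAD
TOIL
TOLD
TOLL
TOMB
TONE
TOOK
TOOL
TORN
TOSS
TOUR
TOWN
TRAP
TRAY
TREE
TRIM
TRIP
TRUE
TUBE
TUCK
TUNE
TURF
TURN
TWIG
TWIN
TYPE
UGLY
UNDO
UNIT
UPON
URGE
USED
USER
VAIN
VASE
VAST
VEIL
VEIN
VENT
VERB
VERY
VEST
VIEW
VINE
VOID
VOTE
WADE
WAGE
WAIT
WAKE
WALK
WALL
WAND
WANT
WARD
WARM
WARN
WASH
WASP
WAVE
WEAK
WEAR
WEED
WEEK
WEEP
WELD
WELL
WENT
WEPT
WERE
WEST
WHAT
WHEN
WHIP
WHOM
WIDE
WIFE
WILD
WILL
WIND
WINE
WING
WINK
WIPE
WIRE
WISE
WISH
WITH
WOLF
WOOD
WOOL
WORD
WORE
WORK
WORM
WORN
WRAP
YARD
YARN
YEAR
YELL
ZEAL
ZERO
ZONE
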