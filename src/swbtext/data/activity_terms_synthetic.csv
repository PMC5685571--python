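activity,word,rating_a,rating_b
religion,church,relevant,relevant
religion,pray,relevant,relevant
religion,prayer,relevant,relevant
religion,god,marginal,relevant
religion,faith,relevant,relevant
religion,blessed,relevant,relevant
religion,worship,marginal,marginal
religion,bible,relevant,relevant
religion,sermon,relevant,relevant
religion,amen,marginal,marginal
holiday,vacation,relevant,relevant
holiday,holiday,relevant,relevant
holiday,beach,relevant,relevant
holiday,trip,relevant,relevant
holiday,travel,marginal,marginal
holiday,christmas,relevant,relevant
holiday,thanksgiving,relevant,relevant
holiday,getaway,marginal,marginal
holiday,resort,relevant,relevant
holiday,sightseeing,marginal,marginal
talk_to_friend,chat,relevant,relevant
talk_to_friend,catch up,relevant,marginal
talk_to_friend,friend,relevant,relevant
talk_to_friend,friends,relevant,relevant
talk_to_friend,gossip,relevant,relevant
talk_to_friend,hangout,relevant,relevant
talk_to_friend,buddy,relevant,marginal
talk_to_friend,pal,relevant,relevant
talk_to_friend,convo,relevant,relevant
talk_to_friend,visiting,relevant,relevant
chores,vacuum,relevant,relevant
chores,dishes,relevant,relevant
chores,laundry,relevant,relevant
chores,cleaning,marginal,relevant
chores,mopping,relevant,relevant
chores,ironing,relevant,marginal
chores,groceries,relevant,relevant
chores,tidying,relevant,relevant
chores,scrubbing,relevant,relevant
chores,chores,relevant,relevant
family,family,relevant,relevant
family,mom,marginal,relevant
family,dad,marginal,relevant
family,sister,relevant,relevant
family,brother,relevant,marginal
family,grandma,relevant,relevant
family,grandpa,marginal,relevant
family,cousin,relevant,relevant
family,kids,relevant,marginal
family,reunion,relevant,relevant
meal,dinner,relevant,relevant
meal,lunch,marginal,relevant
meal,breakfast,relevant,relevant
meal,pizza,relevant,relevant
meal,cooking,relevant,relevant
meal,recipe,relevant,relevant
meal,dessert,relevant,relevant
meal,brunch,relevant,relevant
meal,feast,relevant,relevant
meal,snack,relevant,relevant
school,school,relevant,relevant
school,homework,relevant,relevant
school,exam,relevant,relevant
school,class,relevant,relevant
school,lecture,relevant,relevant
school,semester,relevant,relevant
school,professor,relevant,relevant
school,assignment,marginal,relevant
school,studying,marginal,relevant
school,campus,relevant,relevant
maths,maths,relevant,marginal
maths,math,relevant,relevant
maths,algebra,marginal,marginal
maths,calculus,relevant,relevant
maths,geometry,relevant,relevant
maths,equations,relevant,relevant
maths,statistics,relevant,relevant
maths,trigonometry,relevant,relevant
maths,fractions,relevant,relevant
maths,theorem,relevant,relevant
death_disease,funeral,relevant,relevant
death_disease,cancer,relevant,relevant
death_disease,hospital,relevant,relevant
death_disease,sick,relevant,relevant
death_disease,illness,relevant,relevant
death_disease,disease,relevant,relevant
death_disease,death,relevant,relevant
death_disease,grief,marginal,marginal
death_disease,surgery,relevant,marginal
death_disease,flu,relevant,marginal
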