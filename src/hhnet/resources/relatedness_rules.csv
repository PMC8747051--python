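code_a,code_b,relatedness
adopted_foster_step,adopted_foster_step,0.0
adopted_foster_step,child,0.0
adopted_foster_step,child_in_law,0.0
adopted_foster_step,grandchild,0.0
adopted_foster_step,head,0.0
adopted_foster_step,niece_nephew,0.0
adopted_foster_step,non_relative,0.0
adopted_foster_step,other_relative,0.0
adopted_foster_step,parent,0.0
adopted_foster_step,parent_in_law,0.0
adopted_foster_step,sibling,0.0
adopted_foster_step,spouse,0.0
adopted_foster_step,unspecified,0.0
child,child,0.5
child,child_in_law,0.0
child,grandchild,0.25
child,head,0.5
child,niece_nephew,0.125
child,non_relative,0.0
child,other_relative,0.125
child,parent,0.25
child,parent_in_law,0.25
child,sibling,0.125
child,spouse,0.5
child,unspecified,0.0
child_in_law,child_in_law,0.0
child_in_law,grandchild,0.5
child_in_law,head,0.0
child_in_law,niece_nephew,0.0
child_in_law,non_relative,0.0
child_in_law,other_relative,0.0
child_in_law,parent,0.0
child_in_law,parent_in_law,0.0
child_in_law,sibling,0.0
child_in_law,spouse,0.0
child_in_law,unspecified,0.0
grandchild,grandchild,0.5
grandchild,head,0.25
grandchild,niece_nephew,0.0
grandchild,non_relative,0.0
grandchild,other_relative,0.125
grandchild,parent,0.125
grandchild,parent_in_law,0.125
grandchild,sibling,0.125
grandchild,spouse,0.25
grandchild,unspecified,0.0
head,head,0.0
head,niece_nephew,0.125
head,non_relative,0.0
head,other_relative,0.125
head,parent,0.5
head,parent_in_law,0.0
head,sibling,0.5
head,spouse,0.0
head,unspecified,0.0
niece_nephew,niece_nephew,0.5
niece_nephew,non_relative,0.0
niece_nephew,other_relative,0.125
niece_nephew,parent,0.25
niece_nephew,parent_in_law,0.0
niece_nephew,sibling,0.125
niece_nephew,spouse,0.0
niece_nephew,unspecified,0.0
non_relative,non_relative,0.0
non_relative,other_relative,0.0
non_relative,parent,0.0
non_relative,parent_in_law,0.0
non_relative,sibling,0.0
non_relative,spouse,0.0
non_relative,unspecified,0.0
other_relative,other_relative,0.125
other_relative,parent,0.125
other_relative,parent_in_law,0.0
other_relative,sibling,0.125
other_relative,spouse,0.0
other_relative,unspecified,0.0
parent,parent,0.0
parent,parent_in_law,0.0
parent,sibling,0.5
parent,spouse,0.0
parent,unspecified,0.0
parent_in_law,parent_in_law,0.0
parent_in_law,sibling,0.0
parent_in_law,spouse,0.5
parent_in_law,unspecified,0.0
sibling,sibling,0.5
sibling,spouse,0.0
sibling,unspecified,0.0
spouse,spouse,0.0
spouse,unspecified,0.0
unspecified,unspecified,0.0
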