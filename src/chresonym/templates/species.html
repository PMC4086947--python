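{% extends "base.html" %}
{% block title %}{{ entry.species.binomial }}{% endblock %}
{% block heading %}<em>{{ entry.species.binomial }}</em>{% endblock %}
{% block content %}
<p>Status: {{ entry.species.status }}</p>
{% if entry.species.etymology %}
<p>Etymology: {{ entry.species.etymology }}</p>
{% endif %}
{% if entry.synonyms %}
<h2>Synonyms and other applied names</h2>
<ul>
{% for name in entry.synonyms %}
  <li><a href="{{ links.binomial(name) }}"><em>{{ name }}</em></a></li>
{% endfor %}
</ul>
{% endif %}
<h2>Publications referring to this species</h2>
<ul>
{% for key, names in entry.publications %}
  <li><a href="{{ links.publication(key) }}">{{ key }}</a> as
  {% for name in names %}<em>{{ name }}</em>{{ ", " if not loop.last }}{% endfor %}</li>
{% endfor %}
</ul>
{% endblock %}
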